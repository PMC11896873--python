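"""Seeded synthetic SMILES datasets with known structure-label relationships.

Real transporter bioactivity sets live in external databases; every stage of
this package is instead exercised on generated chemistry whose ground truth
is known by construction.  Molecules are assembled from a small hard-coded
pool of ring scaffolds and substituents.  In the motif benchmark, positives
carry a grafted carboxylic-acid group — a local feature a depth-3
message-passing network can learn, and one that a substructure query can
verify exactly, so the generator is its own oracle.  Optional label noise
flips labels (never structures), keeping the Bayes-optimal separability
analytically known.

These fixtures emulate binary structure-activity data, not real transporter
SAR: property distributions, potency ranges and scaffold frequencies are not
matched to any experimental set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .chem_io import Dataset, MoleculeRecord, standardize_record

CARBOXYLIC_ACID_SMARTS = "[CX3](=O)[OX2H1]"

# Scaffold templates with {r#} substitution slots.  All are free of the
# default motif and yield valid SMILES for every decoration in the pool.
_SCAFFOLDS_DEFAULT = [
    "c1ccc({r1})cc1{r2}",
    "c1cc({r1})ccc1{r2}",
    "C1CCC({r1})CC1{r2}",
    "c1ccc2ccccc2c1{r1}",
    "c1cc({r1})c2ccccc2c1{r2}",
    "c1ccncc1{r1}",
    "c1cc({r1})cnc1{r2}",
    "c1ccoc1{r1}",
    "c1cc({r1})oc1{r2}",
    "c1ccsc1{r1}",
    "C1CCN({r1})CC1",
    "C1CCOC1{r1}",
    "c1ccc2ncccc2c1{r1}",
    "C1CC({r1})CCC1{r2}",
    "c1cnc({r1})cn1",
]

# Substituent pool: motif-free small groups (alkyl, hydroxy/ether, amino,
# halogen, nitrile).
_DECORATIONS = [
    "C", "CC", "CCC", "C(C)C", "CCO", "CO", "OC", "OCC", "OCCO",
    "N", "N(C)C", "CN", "CCN", "C#N", "F", "Cl", "Br", "C(F)(F)F",
]

# Alkyl linkers between scaffold and grafted motif.
_MOTIF_LINKERS = ["", "C", "CC", "CCC", "CCCC", "C(C)", "C(C)(C)"]
_MOTIF_SMILES = "C(=O)O"

# Active family for the similarity benchmark: decorated quinolines.
_ACTIVE_FAMILY = [
    "c1cc({r1})c2ncccc2c1{r2}",
    "c1ccc2nc({r1})ccc2c1{r2}",
]
# Inactive families: scaffolds structurally remote from the quinoline core.
_INACTIVE_FAMILY = [
    "c1ccc({r1})cc1{r2}",
    "C1CCC({r1})CC1{r2}",
    "c1ccoc1{r1}",
    "c1ccsc1{r1}",
    "C1CCN({r1})CC1",
    "C1CCOC1{r1}",
    "c1cnc({r1})cn1",
    "C1CC({r1})CCC1{r2}",
]

FRAGMENT_POOLS = {"default": _SCAFFOLDS_DEFAULT}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic motif-classification dataset."""

    n_compounds: int = 600
    motif_smarts: str = CARBOXYLIC_ACID_SMARTS
    positive_fraction: float = 0.5
    label_noise: float = 0.0
    seed: int = 0
    fragment_pool_id: str = "default"

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.fragment_pool_id not in FRAGMENT_POOLS:
            raise ValueError(f"unknown fragment pool {self.fragment_pool_id!r}")


def _slots(template: str) -> list[str]:
    return re.findall(r"\{(r\d)\}", template)


def _assemble(rng: np.random.Generator, templates: list[str], positive: bool) -> str:
    template = templates[rng.integers(len(templates))]
    slots = _slots(template)
    fills = {s: _DECORATIONS[rng.integers(len(_DECORATIONS))] for s in slots}
    if positive:
        linker = _MOTIF_LINKERS[rng.integers(len(_MOTIF_LINKERS))]
        fills[slots[rng.integers(len(slots))]] = linker + _MOTIF_SMILES
    return template.format(**fills)


def generate_motif_dataset(spec: FixtureSpec) -> Dataset:
    """Generate a standardized, deduplicated binary classification dataset.

    Structural positives contain the motif (grafted at a scaffold slot via a
    random alkyl linker); negatives are verified motif-free by substructure
    match.  The reported label equals the structural label flipped
    independently with probability ``label_noise``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    motif = Chem.MolFromSmarts(spec.motif_smarts)
    if motif is None:
        raise ValueError(f"invalid motif SMARTS {spec.motif_smarts!r}")
    templates = FRAGMENT_POOLS[spec.fragment_pool_id]
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    # The class of each record is drawn once (Bernoulli positive_fraction);
    # structure assembly then retries until a unique valid molecule of that
    # class is found, so duplicate rejection cannot skew the class balance.
    per_record_budget = 500
    for idx in range(spec.n_compounds):
        want_positive = bool(rng.random() < spec.positive_fraction)
        for _ in range(per_record_budget):
            smi = _assemble(rng, templates, want_positive)
            rep = standardize_record(smi, f"syn-{idx:05d}", provenance="synthetic")
            if not rep.valid:
                continue
            canon = rep.record.canonical_smiles
            if canon in seen:
                continue
            mol = Chem.MolFromSmiles(canon)
            if mol.HasSubstructMatch(motif) != want_positive:
                continue
            label = int(want_positive) ^ int(rng.random() < spec.label_noise)
            seen.add(canon)
            records.append(replace(rep.record, label=label))
            break
        else:
            raise RuntimeError(
                f"generation shortfall: {len(records)}/{spec.n_compounds} unique "
                f"molecules (structure retry budget exhausted)"
            )
    return Dataset(records=records, name=f"motif-{spec.seed}", mode="inhibitor")


def structural_labels(dataset: Dataset, motif_smarts: str = CARBOXYLIC_ACID_SMARTS) -> list[int]:
    """Ground-truth motif presence per record (the generator's own oracle)."""
    motif = Chem.MolFromSmarts(motif_smarts)
    out = []
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        out.append(int(mol.HasSubstructMatch(motif)))
    return out


def _generate_family(
    rng: np.random.Generator,
    templates: list[str],
    n: int,
    seen: set[str],
    id_prefix: str,
    provenance: str,
) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    budget = 500 * n
    attempts = 0
    while len(records) < n and attempts < budget:
        attempts += 1
        smi = _assemble(rng, templates, positive=False)
        rep = standardize_record(smi, f"{id_prefix}-{len(records):04d}", provenance=provenance)
        if not rep.valid or rep.record.canonical_smiles in seen:
            continue
        seen.add(rep.record.canonical_smiles)
        records.append(rep.record)
    if len(records) < n:
        raise RuntimeError(f"generation shortfall for {id_prefix}: {len(records)}/{n}")
    return records


def generate_similarity_benchmark(
    seed: int,
    n_reference: int = 20,
    n_active: int = 50,
    n_inactive: int = 150,
) -> tuple[Dataset, Dataset]:
    """Reference set plus an external potency-labeled set for screen evaluation.

    Reference compounds and external actives are decorated variants of one
    quinoline scaffold family (external actives assigned potencies below
    1 µM); inactives come from disjoint scaffold families with potencies
    above 10 µM.  Reference and external sets share no canonical SMILES.
    """
    if min(n_reference, n_active, n_inactive) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    family = _generate_family(
        rng, _ACTIVE_FAMILY, n_reference + n_active, seen, "act", "synthetic-benchmark"
    )
    reference = [replace(r, label=1) for r in family[:n_reference]]
    actives = [
        replace(r, potency=float(10 ** rng.uniform(-8.0, -6.0)))
        for r in family[n_reference:]
    ]
    inactive = [
        replace(r, potency=float(10 ** rng.uniform(-5.0, -4.0)))
        for r in _generate_family(
            rng, _INACTIVE_FAMILY, n_inactive, seen, "inact", "synthetic-benchmark"
        )
    ]
    ref_ds = Dataset(records=reference, name=f"simref-{seed}", mode="inhibitor")
    ext_ds = Dataset(records=actives + inactive, name=f"simext-{seed}", mode="inhibitor")
    return ref_ds, ext_ds
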