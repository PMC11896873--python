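"""Reading, standardizing, deduplicating and writing SMILES datasets.

All model-facing code consumes :class:`Dataset` objects whose records have
passed :func:`standardize_record`.  Standardization mirrors the conventional
structure-curation pipeline: validity check, normalization of functional-group
conventions and charges, and salt stripping (largest organic fragment kept).
The canonical SMILES written by this module is a fixed point of the pipeline,
so datasets round-trip losslessly through CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty about every malformed SMILES; invalid rows are reported
# through StandardizationReport / the skip log instead.
RDLogger.DisableLog("rdApp.*")

DATASET_MODES = ("inhibitor", "substrate", "unlabeled")


@dataclass
class MoleculeRecord:
    """One compound: the unit of every dataset.

    ``canonical_smiles`` is ``None`` until standardization succeeds.  ``label``
    is the binary activity (1 active / 0 inactive) or ``None`` for query
    compounds.  ``potency`` optionally carries a measured concentration in
    molar units, used only by the similarity-screen evaluation.
    """

    record_id: str
    input_smiles: str
    canonical_smiles: Optional[str] = None
    label: Optional[int] = None
    provenance: str = ""
    potency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class StandardizationReport:
    record: MoleculeRecord
    valid: bool
    actions: list[str] = field(default_factory=list)
    reject_reason: Optional[str] = None


@dataclass
class DeduplicationReport:
    n_input: int = 0
    n_kept: int = 0
    n_merged: int = 0
    conflicts: list[str] = field(default_factory=list)

    @property
    def n_conflict_records(self) -> int:
        return self.n_input - self.n_kept - self.n_merged


@dataclass
class Dataset:
    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = ""
    mode: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.mode not in DATASET_MODES:
            raise ValueError(f"mode must be one of {DATASET_MODES}, got {self.mode!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    @property
    def smiles(self) -> list[Optional[str]]:
        return [r.canonical_smiles for r in self.records]

    def subset(self, indices: Sequence[int], name: Optional[str] = None) -> "Dataset":
        return Dataset(
            records=[self.records[i] for i in indices],
            name=name if name is not None else self.name,
            mode=self.mode,
        )


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_record(
    smiles: str,
    record_id: str,
    label: Optional[int] = None,
    provenance: str = "",
    potency: Optional[float] = None,
) -> StandardizationReport:
    """Validate, normalize and salt-strip one SMILES.

    The pipeline is: parse (validity check) -> structural normalization
    (functional-group conventions, reionization) -> keep the largest organic
    fragment (salt strip; ties broken by heavy-atom count then lexicographic
    canonical SMILES) -> neutralize charges -> canonical isomeric SMILES.
    Stereochemistry present in the input is preserved.

    Returns a report; ``valid=False`` carries ``reject_reason`` of
    ``"parse_error"``, ``"no_organic_fragment"`` or ``"empty_input"`` and no
    canonical SMILES.
    """
    record = MoleculeRecord(
        record_id=record_id,
        input_smiles=smiles,
        label=label,
        provenance=provenance,
        potency=potency,
    )
    if not smiles or not smiles.strip():
        return StandardizationReport(record, False, ["rejected"], "empty_input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationReport(record, False, ["checked", "rejected"], "parse_error")
    actions = ["checked"]
    try:
        mol = rdMolStandardize.Cleanup(mol)
    except Exception:  # pragma: no cover - rdkit-internal failure
        return StandardizationReport(record, False, ["checked", "rejected"], "parse_error")
    actions.append("standardized")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        organic = [f for f in frags if _has_carbon(f)]
        if not organic:
            return StandardizationReport(
                record, False, actions + ["rejected"], "no_organic_fragment"
            )
        organic.sort(key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
        mol = organic[0]
        actions.append("salt_stripped")
    elif not _has_carbon(mol):
        return StandardizationReport(
            record, False, actions + ["rejected"], "no_organic_fragment"
        )

    mol = _UNCHARGER.uncharge(mol)
    canonical = Chem.MolToSmiles(mol)
    if not canonical:
        return StandardizationReport(record, False, actions + ["rejected"], "parse_error")
    record = replace(record, canonical_smiles=canonical)
    return StandardizationReport(record, True, actions, None)


def deduplicate(dataset: Dataset) -> tuple[Dataset, DeduplicationReport]:
    """Collapse exact duplicates; drop all copies of label-conflicting ones.

    Records sharing a canonical SMILES and a consistent label are merged to
    the first occurrence.  Records sharing a canonical SMILES but carrying
    conflicting binary labels are removed entirely and their structure listed
    in the report.  Output preserves first-occurrence order.
    """
    report = DeduplicationReport(n_input=len(dataset.records))
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in dataset.records:
        if rec.canonical_smiles is None:
            raise ValueError(f"record {rec.record_id!r} is not standardized")
        if rec.canonical_smiles not in groups:
            groups[rec.canonical_smiles] = []
            order.append(rec.canonical_smiles)
        groups[rec.canonical_smiles].append(rec)

    kept: list[MoleculeRecord] = []
    for smi in order:
        group = groups[smi]
        labels = {r.label for r in group if r.label is not None}
        if len(labels) > 1:
            report.conflicts.append(smi)
            continue
        keep = group[0]
        if keep.label is None and labels:
            keep = replace(keep, label=labels.pop())
        kept.append(keep)
        report.n_merged += len(group) - 1
    report.n_kept = len(kept)
    out = Dataset(records=kept, name=dataset.name, mode=dataset.mode)
    return out, report


def from_smiles(
    smiles_list: Iterable[str],
    labels: Optional[Iterable[Optional[int]]] = None,
    name: str = "",
    mode: str = "unlabeled",
    provenance: str = "",
    id_prefix: str = "cmpd",
) -> tuple[Dataset, list[StandardizationReport]]:
    """Standardize an in-memory SMILES collection into a Dataset.

    Invalid entries are skipped (their reports are still returned).
    """
    smiles_list = list(smiles_list)
    labels_list = list(labels) if labels is not None else [None] * len(smiles_list)
    records: list[MoleculeRecord] = []
    reports: list[StandardizationReport] = []
    for i, (smi, lab) in enumerate(zip(smiles_list, labels_list)):
        rep = standardize_record(
            smi, f"{id_prefix}-{i:05d}", label=lab, provenance=provenance
        )
        reports.append(rep)
        if rep.valid:
            records.append(rep.record)
    return Dataset(records=records, name=name, mode=mode), reports


def read_dataset(path, mode: str = "unlabeled", name: Optional[str] = None) -> Dataset:
    """Read a SMILES CSV (columns ``smiles``; optional ``activity``, ``id``).

    Every row passes through :func:`standardize_record`; invalid rows are
    skipped with a logged count.  An ``activity`` value outside {0, 1, empty}
    is a hard error naming the offending row.
    """
    df = pd.read_csv(path, dtype={"smiles": str})
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: required column 'smiles' is missing")
    has_activity = "activity" in df.columns
    has_potency = "potency" in df.columns
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for i, row in df.iterrows():
        label: Optional[int] = None
        if has_activity and not pd.isna(row["activity"]):
            raw = row["activity"]
            if float(raw) not in (0.0, 1.0):
                raise ValueError(
                    f"{path}: row {i}: activity must be 0 or 1, got {raw!r}"
                )
            label = int(raw)
        rid = str(row["id"]) if "id" in df.columns and not pd.isna(row["id"]) else f"row-{i}"
        potency = None
        if has_potency and not pd.isna(row["potency"]):
            potency = float(row["potency"])
        rep = standardize_record(
            str(row["smiles"]), rid, label=label, provenance=str(path), potency=potency
        )
        if not rep.valid:
            n_skipped += 1
            logger.warning(
                "%s: row %d (%r) skipped: %s", path, i, row["smiles"], rep.reject_reason
            )
            continue
        records.append(rep.record)
    if n_skipped:
        logger.info("%s: skipped %d invalid row(s)", path, n_skipped)
    return Dataset(records=records, name=name or str(path), mode=mode)


def read_smiles_list(path, name: Optional[str] = None) -> Dataset:
    """Read a plain text file with one SMILES per line (unlabeled queries)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    ds, _ = from_smiles(lines, name=name or str(path), provenance=str(path), id_prefix="query")
    return ds


def write_dataset(dataset: Dataset, path) -> None:
    """Write a standardized dataset as CSV (round-trips through read_dataset).

    The ``activity`` column is emitted only when at least one record carries a
    label; ``potency`` likewise.
    """
    rows = []
    any_label = any(r.label is not None for r in dataset.records)
    any_potency = any(r.potency is not None for r in dataset.records)
    for rec in dataset.records:
        if rec.canonical_smiles is None:
            raise ValueError(f"record {rec.record_id!r} is not standardized")
        row = {"id": rec.record_id, "smiles": rec.canonical_smiles}
        if any_label:
            row["activity"] = rec.label
        if any_potency:
            row["potency"] = rec.potency
        rows.append(row)
    cols = ["id", "smiles"] + (["activity"] if any_label else []) + (
        ["potency"] if any_potency else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
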