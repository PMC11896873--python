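"""Morgan fingerprints, Tanimoto similarity, and the MAX reference-set score.

The similarity screen scores a query by its maximum Tanimoto similarity to
any member of a target's reference set; the same radius-2 circular
fingerprints feed the SDC applicability-domain score, so a model's similarity
and domain geometry are always computed in one bit space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Dataset, MoleculeRecord

DEFAULT_RADIUS = 2
DEFAULT_WIDTH = 2048


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint as the set of on-bit indices."""

    bits: frozenset
    width: int = DEFAULT_WIDTH
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.width):
            raise ValueError("bit index outside [0, width)")


@dataclass(frozen=True)
class SimilarityResult:
    query_id: str
    max_score: float
    argmax_reference_id: str


def fingerprint(
    record: Union[MoleculeRecord, str],
    radius: int = DEFAULT_RADIUS,
    width: int = DEFAULT_WIDTH,
) -> Fingerprint:
    """Morgan (circular) fingerprint of a standardized record.

    Accepts a :class:`MoleculeRecord` (must carry ``canonical_smiles``) or a
    SMILES string assumed already canonical.  Deterministic: identical
    canonical SMILES give identical bit sets.
    """
    if isinstance(record, MoleculeRecord):
        smiles = record.canonical_smiles
        if smiles is None:
            raise ValueError(f"unstandardized input: record {record.record_id!r}")
    else:
        smiles = record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unstandardized input: {smiles!r} does not parse")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), width=width, radius=radius)


def fingerprint_dataset(
    dataset: Union[Dataset, Iterable[MoleculeRecord]],
    radius: int = DEFAULT_RADIUS,
    width: int = DEFAULT_WIDTH,
) -> list[Fingerprint]:
    return [fingerprint(rec, radius=radius, width=width) for rec in dataset]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two bit sets.

    Two empty fingerprints are defined as identical (similarity 1); an empty
    against a non-empty fingerprint is 0 by the formula.
    """
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} vs {b.width}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    return 1.0 - tanimoto(a, b)


def max_similarity(
    query: Fingerprint,
    reference: Sequence[Fingerprint],
    reference_ids: Optional[Sequence[str]] = None,
    query_id: str = "",
) -> SimilarityResult:
    """MAX score: maximum Tanimoto similarity of the query over a reference set.

    Ties in the argmax are broken by first position in the reference order.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference set")
    if reference_ids is None:
        reference_ids = [str(i) for i in range(len(reference))]
    best_score = -1.0
    best_id = reference_ids[0]
    for ref, rid in zip(reference, reference_ids):
        s = tanimoto(query, ref)
        if s > best_score:
            best_score = s
            best_id = rid
    return SimilarityResult(query_id=query_id, max_score=best_score, argmax_reference_id=str(best_id))
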