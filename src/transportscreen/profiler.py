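"""Per-target model registry and batch screening profiles.

A registry maps each (transporter, mode) endpoint to either a trained
message-passing ensemble ("gcnn" approach) or a reference compound set
scored by maximum Tanimoto similarity ("similarity" approach).  Batch
profiling scores every query against every registered endpoint, attaches the
SDC applicability-domain value and in/out-of-domain flag computed against
that endpoint's training or reference chemistry, and writes the result as
call matrices (inhibitor / substrate, with and without domain masking) plus
one long-format table.

The shipped default registry covers the 12 transporters regulators recommend
screening (Pgp, BCRP, MRP1, BSEP, MRP2, OATP1B1, OATP1B3, OAT1, OAT3, OCT2,
MATE-1, MATE-2K), with the network approach on the six inhibitor and three
substrate endpoints that have enough public data and the similarity approach
on the remaining fifteen.  Artifact paths in the default file are null:
users train models / point at reference CSVs locally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .applicability import DEFAULT_AD_PERCENTILE, calibrate_threshold, sdc_score
from .chem_io import Dataset, read_dataset
from .dmpnn import DMPNNConfig, featurize, load_ensemble, predict_member, save_ensemble, train_ensemble
from .fingerprints import Fingerprint, fingerprint, fingerprint_dataset, max_similarity

logger = logging.getLogger(__name__)

MASK_SENTINEL = "OUT_OF_DOMAIN"
DEFAULT_SIMILARITY_THRESHOLD = 0.5


@dataclass
class TransporterModelSpec:
    target_name: str
    gene_symbol: str
    mode: str  # inhibitor | substrate
    approach: str  # gcnn | similarity
    model_path: Optional[str] = None
    reference_set_path: Optional[str] = None
    similarity_call_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    ad_threshold: Optional[float] = None
    fingerprint_radius: int = 2
    fingerprint_width: int = 2048

    def __post_init__(self) -> None:
        if self.mode not in ("inhibitor", "substrate"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.approach not in ("gcnn", "similarity"):
            raise ValueError(f"invalid approach {self.approach!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.target_name, self.mode)

    @property
    def artifact_path(self) -> Optional[str]:
        return self.model_path if self.approach == "gcnn" else self.reference_set_path


@dataclass
class Registry:
    specs: list[TransporterModelSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def counts(self) -> dict:
        out: dict = {"gcnn": 0, "similarity": 0}
        for s in self.specs:
            out[s.approach] += 1
        return out


def default_registry_path() -> Path:
    return Path(resources.files("transportscreen") / "data" / "default_registry.json")


def load_registry(config_path=None, check_artifacts: bool = True) -> Registry:
    """Load and validate a registry JSON (default: the shipped 24-model file).

    (target, mode) pairs must be unique.  When ``check_artifacts`` is true,
    any non-null artifact path must exist on disk; null paths are allowed
    (endpoint declared but not materialized) and rejected only at profiling
    time.
    """
    path = Path(config_path) if config_path is not None else default_registry_path()
    raw = json.loads(Path(path).read_text())
    entries = raw.get("targets", raw if isinstance(raw, list) else [])
    specs = [TransporterModelSpec(**e) for e in entries]
    seen = set()
    for spec in specs:
        if spec.key in seen:
            raise ValueError(f"duplicate (target, mode) entry: {spec.key}")
        seen.add(spec.key)
        if check_artifacts and spec.artifact_path is not None:
            if not Path(spec.artifact_path).exists():
                raise FileNotFoundError(
                    f"{spec.target_name}/{spec.mode}: missing artifact {spec.artifact_path}"
                )
    if not specs:
        logger.warning("%s: empty registry", path)
    return Registry(specs=specs)


def build_gcnn_model(
    dataset: Dataset,
    out_dir,
    config: Optional[DMPNNConfig] = None,
    ad_percentile: float = DEFAULT_AD_PERCENTILE,
) -> dict:
    """Train an ensemble on a labeled dataset and write a model directory.

    The applicability-domain threshold is calibrated on the training
    fingerprints (leave-one-out SDC percentile) and stored with the model.
    """
    config = config or DMPNNConfig()
    ensemble = train_ensemble(dataset, config)
    fps = fingerprint_dataset(dataset)
    threshold = calibrate_threshold(fps, percentile=ad_percentile)
    ad_meta = {
        "threshold": threshold,
        "percentile": ad_percentile,
        "n_training": len(dataset),
        "fingerprint_radius": 2,
        "fingerprint_width": 2048,
    }
    save_ensemble(ensemble, out_dir, ad_metadata=ad_meta)
    return ad_meta


@dataclass
class _LoadedModel:
    spec: TransporterModelSpec
    training_fps: list[Fingerprint]
    training_ids: list[str]
    ad_threshold: float
    ensemble: Optional[object] = None  # TrainedEnsemble for gcnn
    call_threshold: float = 0.5


def _load_model(spec: TransporterModelSpec) -> _LoadedModel:
    if spec.artifact_path is None:
        raise ValueError(
            f"{spec.target_name}/{spec.mode}: no artifact configured for profiling"
        )
    if spec.approach == "gcnn":
        ensemble, ad_meta = load_ensemble(spec.model_path)
        fps = [
            fingerprint(s, radius=spec.fingerprint_radius, width=spec.fingerprint_width)
            for s in ensemble.training_smiles
        ]
        threshold = spec.ad_threshold
        if threshold is None:
            threshold = ad_meta.get("threshold")
        if threshold is None:
            threshold = calibrate_threshold(fps)
        return _LoadedModel(
            spec=spec,
            training_fps=fps,
            training_ids=[str(i) for i in range(len(fps))],
            ad_threshold=float(threshold),
            ensemble=ensemble,
            call_threshold=ensemble.config.call_threshold,
        )
    reference = read_dataset(spec.reference_set_path, mode=spec.mode)
    fps = fingerprint_dataset(
        reference, radius=spec.fingerprint_radius, width=spec.fingerprint_width
    )
    threshold = spec.ad_threshold
    if threshold is None:
        threshold = calibrate_threshold(fps)
    return _LoadedModel(
        spec=spec,
        training_fps=fps,
        training_ids=[r.record_id for r in reference.records],
        ad_threshold=float(threshold),
        call_threshold=spec.similarity_call_threshold,
    )


@dataclass
class ScreeningProfile:
    """Long-format profile: one row per (query, target, mode)."""

    table: pd.DataFrame

    COLUMNS = [
        "query_id", "input_smiles", "canonical_smiles", "target", "gene_symbol",
        "mode", "approach", "score", "call", "sdc", "ad_threshold", "in_domain",
        "status",
    ]

    def __len__(self) -> int:
        return len(self.table)


def profile_batch(
    queries: Dataset,
    registry: Registry,
    batch_limit: Optional[int] = None,
    invalid_queries: Optional[list] = None,
) -> ScreeningProfile:
    """Score every query against every registered endpoint.

    gcnn endpoints report the ensemble mean probability with the model's
    probability-threshold call; similarity endpoints report the MAX Tanimoto
    score with the spec's similarity threshold.  Every row carries the SDC
    against that endpoint's training/reference fingerprints and the
    in-domain flag.  Invalid queries (standardization rejects passed via
    ``invalid_queries`` as StandardizationReports) are emitted with a
    ``rejected:<reason>`` status instead of being dropped.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    n_total = len(queries) + len(invalid_queries or [])
    if batch_limit is not None and n_total > batch_limit:
        raise ValueError(f"batch of {n_total} queries exceeds limit {batch_limit}")

    models = [_load_model(spec) for spec in registry]
    rows: list[dict] = []
    graphs = [featurize(r) for r in queries.records]
    query_fps_cache: dict[tuple[int, int], list[Fingerprint]] = {}

    for model in models:
        spec = model.spec
        fp_key = (spec.fingerprint_radius, spec.fingerprint_width)
        if fp_key not in query_fps_cache:
            query_fps_cache[fp_key] = [
                fingerprint(r, radius=fp_key[0], width=fp_key[1]) for r in queries.records
            ]
        q_fps = query_fps_cache[fp_key]
        if spec.approach == "gcnn":
            member_probs = np.stack(
                [predict_member(m, graphs, model.ensemble.config) for m in model.ensemble.members]
            ) if graphs else np.zeros((1, 0))
            scores = member_probs.mean(axis=0)
        else:
            scores = np.array(
                [
                    max_similarity(fp, model.training_fps, model.training_ids).max_score
                    for fp in q_fps
                ]
            )
        for i, rec in enumerate(queries.records):
            sdc = sdc_score(q_fps[i], model.training_fps)
            score = float(scores[i])
            rows.append(
                {
                    "query_id": rec.record_id,
                    "input_smiles": rec.input_smiles,
                    "canonical_smiles": rec.canonical_smiles,
                    "target": spec.target_name,
                    "gene_symbol": spec.gene_symbol,
                    "mode": spec.mode,
                    "approach": spec.approach,
                    "score": score,
                    "call": "active" if score >= model.call_threshold else "inactive",
                    "sdc": sdc,
                    "ad_threshold": model.ad_threshold,
                    "in_domain": bool(sdc >= model.ad_threshold),
                    "status": "ok",
                }
            )
        for rep in invalid_queries or []:
            rows.append(
                {
                    "query_id": rep.record.record_id,
                    "input_smiles": rep.record.input_smiles,
                    "canonical_smiles": None,
                    "target": spec.target_name,
                    "gene_symbol": spec.gene_symbol,
                    "mode": spec.mode,
                    "approach": spec.approach,
                    "score": np.nan,
                    "call": "",
                    "sdc": np.nan,
                    "ad_threshold": model.ad_threshold,
                    "in_domain": False,
                    "status": f"rejected:{rep.reject_reason}",
                }
            )
    table = pd.DataFrame(rows, columns=ScreeningProfile.COLUMNS)
    return ScreeningProfile(table=table)


def _call_matrix(table: pd.DataFrame, mode: str, masked: bool) -> pd.DataFrame:
    sub = table[(table["mode"] == mode) & (table["status"] == "ok")]
    if sub.empty:
        return pd.DataFrame()
    calls = sub.copy()
    if masked:
        calls.loc[~calls["in_domain"], "call"] = MASK_SENTINEL
    matrix = calls.pivot_table(
        index="query_id", columns="target", values="call", aggfunc="first", sort=False
    )
    return matrix


def write_profile(profile: ScreeningProfile, out_dir, manifest: Optional[dict] = None) -> dict:
    """Write the four call matrices, the long table, and a run manifest.

    Matrices: ``{inhibitor,substrate}_calls.csv`` (unmasked) and
    ``{inhibitor,substrate}_calls_ad.csv`` (out-of-domain cells replaced by
    the ``OUT_OF_DOMAIN`` sentinel).  Output is byte-stable for fixed input.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    profile.table.to_csv(out / "profile_long.csv", index=False)
    written["long"] = out / "profile_long.csv"
    for mode in ("inhibitor", "substrate"):
        for masked, suffix in ((False, "calls"), (True, "calls_ad")):
            matrix = _call_matrix(profile.table, mode, masked)
            fname = out / f"{mode}_{suffix}.csv"
            matrix.to_csv(fname)
            written[f"{mode}_{suffix}"] = fname
    info = {"version": __version__, "n_rows": len(profile)}
    if manifest:
        info.update(manifest)
    (out / "manifest.json").write_text(json.dumps(info, indent=1, default=str))
    written["manifest"] = out / "manifest.json"
    return written


def read_profile(path) -> ScreeningProfile:
    """Re-load a long-format profile CSV written by :func:`write_profile`."""
    table = pd.read_csv(Path(path), dtype={"call": str, "status": str})
    table["call"] = table["call"].fillna("")
    return ScreeningProfile(table=table)
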