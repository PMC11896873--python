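"""SDC applicability domain: sum of distance-weighted contributions.

A query's SDC against a model's training set is

    SDC = sum_i exp(-3 * TD_i / (1 - TD_i)),    TD_i = 1 - Tanimoto(query, i)

over the n training molecules.  Each term lies in (0, 1]: it is 1 when the
query duplicates a training molecule (TD = 0) and decays rapidly as the
Tanimoto distance grows; a TD of exactly 1 contributes 0, the continuous
limit of the expression.  A large SDC therefore means the query sits in a
densely covered region of the training chemistry, and predictions there are
considered reliable.

The paper this class of score comes from applies it without publishing a
numeric cutoff, so the in/out-of-domain threshold here is self-calibrated:
the default is a low percentile of the training set's own leave-one-out SDC
distribution, stored with the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fingerprints import Fingerprint, tanimoto

SDC_STEEPNESS = 3.0  # the fixed -3 coefficient in the exponential weight
DEFAULT_AD_PERCENTILE = 0.05


@dataclass(frozen=True)
class ADResult:
    query_id: str
    sdc: float
    n_training: int
    threshold: float
    in_domain: bool


def _sdc_term(td: float) -> float:
    if td >= 1.0:
        return 0.0
    return math.exp(-SDC_STEEPNESS * td / (1.0 - td))


def sdc_score(query: Fingerprint, training: Sequence[Fingerprint]) -> float:
    """SDC of one query against a non-empty training fingerprint set."""
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    return float(sum(_sdc_term(1.0 - tanimoto(query, t)) for t in training))


def calibrate_threshold(
    training: Sequence[Fingerprint],
    percentile: float = DEFAULT_AD_PERCENTILE,
) -> float:
    """In-domain SDC threshold from the leave-one-out training distribution.

    Each training molecule is scored against the other n-1; the given
    percentile (default 0.05, i.e. the value only 5% of the training set
    itself falls below) becomes the cutoff.  Deterministic.
    """
    training = list(training)
    if len(training) < 3:
        raise ValueError("insufficient training set: need at least 3 members")
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile must lie in [0, 1]")
    loo = []
    for i, fp in enumerate(training):
        rest = training[:i] + training[i + 1 :]
        loo.append(sdc_score(fp, rest))
    return float(np.quantile(np.asarray(loo), percentile))


def domain_flag(
    query: Fingerprint,
    training: Sequence[Fingerprint],
    threshold: float,
    query_id: str = "",
) -> ADResult:
    """Score a query's SDC and flag it in-domain iff SDC >= threshold."""
    sdc = sdc_score(query, training)
    return ADResult(
        query_id=query_id,
        sdc=sdc,
        n_training=len(list(training)),
        threshold=float(threshold),
        in_domain=sdc >= threshold,
    )
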