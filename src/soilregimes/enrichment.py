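"""Empirical replicate-noise model and z-score enrichment calling.

Replicate-to-replicate scatter of ASV counts is described by an effective
Gaussian model: a measurement of an ASV with mean abundance ``n`` counts has
standard deviation sigma(n) = sqrt((c_frac*n)^2 + c0^2), combining fractional
noise c_frac with a constant floor c0 (counts).  The model is fitted
empirically per (soil, perturbed pH), since those sample sets are processed in
independent sequencing runs.

Enrichment of an ASV in the untreated vs chloramphenicol arm is scored by
z = (abs- - abs+)/sigma per replicate pair (median over the three pairs), and
called against a two-tailed Bonferroni critical value
z_crit = Phi^-1(1 - alpha/(2 n_ASV)).  ASVs also enriched in the no-nitrate
contrast ("NNresponders") are filtered as false-positive nitrate responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "NoiseModel",
    "EnrichmentCall",
    "noise_sd",
    "fit_noise_model",
    "critical_z",
    "enrichment_zscores",
    "call_enriched",
]

Z_PSEUDO = 0.5  # pseudocount on raw counts before spike normalization
SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class NoiseModel:
    """sigma(n) = sqrt((c_frac*n)^2 + c0^2), per-replicate count noise."""

    c_frac: float
    c0: float
    soil_id: str | None = None
    perturbed_ph: float | None = None

    def __post_init__(self) -> None:
        if self.c_frac < 0 or self.c0 < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class EnrichmentCall:
    """Called ASVs for one regime."""

    regime: str
    enriched: set
    nn_responders: set = field(default_factory=set)
    z: pd.DataFrame | None = None  # per-condition median z for the regime's conditions
    z_crit: dict = field(default_factory=dict)


def noise_sd(n, model: NoiseModel):
    """Per-replicate count standard deviation at mean count ``n``."""
    n = np.asarray(n, float)
    return np.sqrt((model.c_frac * n) ** 2 + model.c0**2)


def fit_noise_model(replicate_counts: pd.DataFrame | np.ndarray,
                    high_thresh: float = 50.0, coverage: float = 0.67,
                    c0_max: float = 100.0,
                    fallback: NoiseModel | None = None,
                    soil_id: str | None = None,
                    perturbed_ph: float | None = None) -> NoiseModel:
    """Fit (c_frac, c0) from replicate x ASV counts.

    ``c_frac`` is the robust spread of pairwise relative differences among
    ASVs with pair-mean count above ``high_thresh`` (median absolute relative
    difference scaled by 1.4826/sqrt(2) to the per-replicate Gaussian sd).
    ``c0`` is then the smallest value for which the stated fraction of all
    replicate-pair comparisons fall within +/- sigma(c0, c_frac) (one-sigma
    deviations of the pair difference, i.e. |n1-n2|/sqrt(2) <= sigma), found by
    monotone bisection.
    """
    X = np.asarray(replicate_counts, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a replicate x ASV array with >= 2 replicates")
    pairs = list(combinations(range(X.shape[0]), 2))
    d = np.concatenate([X[i] - X[j] for i, j in pairs])
    m = np.concatenate([(X[i] + X[j]) / 2.0 for i, j in pairs])

    hi = m > high_thresh
    if hi.sum() < 10:
        if fallback is None:
            raise ValueError("too few high-abundance ASVs to estimate c_frac")
        c_frac = fallback.c_frac
    else:
        rel = np.abs(d[hi] / m[hi])
        c_frac = float(np.median(rel) * 1.4826 / SQRT2)

    # coverage(c0) is monotone increasing; bisect the smallest c0 reaching it
    scaled = np.abs(d) / SQRT2

    def cov(c0):
        return np.mean(scaled <= np.sqrt((c_frac * m) ** 2 + c0**2))

    if cov(0.0) >= coverage:
        c0 = 0.0
    elif cov(c0_max) < coverage:
        c0 = c0_max
    else:
        lo_b, hi_b = 0.0, c0_max
        for _ in range(60):
            mid = 0.5 * (lo_b + hi_b)
            if cov(mid) >= coverage:
                hi_b = mid
            else:
                lo_b = mid
        c0 = hi_b
    return NoiseModel(c_frac=c_frac, c0=float(c0), soil_id=soil_id, perturbed_ph=perturbed_ph)


def critical_z(alpha: float = 0.05, n_asv: int = 2000) -> float:
    """Two-tailed Bonferroni critical z: Phi^-1(1 - alpha/(2 n_ASV))."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_asv < 1:
        raise ValueError("n_asv must be >= 1")
    return float(norm.ppf(1.0 - alpha / (2.0 * n_asv)))


def enrichment_zscores(minus_counts: pd.DataFrame, plus_counts: pd.DataFrame,
                       spike_minus: np.ndarray, spike_plus: np.ndarray,
                       model: NoiseModel, pseudo: float = Z_PSEUDO) -> pd.Series:
    """Per-ASV median z over matched replicate pairs.

    Counts are augmented by the 0.5 pseudocount and spike-normalized to
    absolute abundance; the abundance difference is mapped back to the
    chloramphenicol arm's count scale (where the noise model lives) and
    divided by the null standard deviation of the difference: the reference
    (chl+) abundance's count noise evaluated at each arm's own spike depth,
    sqrt(sigma(n+)^2 + (S+/S-)^2 sigma(n+ S-/S+)^2).  With equal spike depths
    this is sqrt(2)*sigma(n+), making z standard normal under the null that
    both arms share one abundance distribution (the premise of the Bonferroni
    critical value), while large enrichments are not penalized by their own
    noise.  ASVs at exactly 0 counts in both samples of a pair get z = 0 for
    that pair.

    ``minus_counts``/``plus_counts``: replicate x ASV raw counts, row k of one
    arm paired with row k of the other.  ``spike_*``: per-replicate spike-in
    counts.
    """
    if minus_counts.shape != plus_counts.shape:
        raise ValueError("arms must have matching replicate x ASV shapes")
    Xm = np.asarray(minus_counts, float)
    Xp = np.asarray(plus_counts, float)
    sm = np.asarray(spike_minus, float).reshape(-1, 1)
    sp = np.asarray(spike_plus, float).reshape(-1, 1)
    if sm.shape[0] != Xm.shape[0] or sp.shape[0] != Xp.shape[0]:
        raise ValueError("one spike count per replicate is required")
    abs_m = (Xm + pseudo) / sm
    abs_p = (Xp + pseudo) / sp
    n_ref = Xp + pseudo  # reference abundance on the chl+ count scale
    n_ref_minus = n_ref * sm / sp  # the same abundance at the chl- depth
    den = np.sqrt(noise_sd(n_ref, model) ** 2
                  + (sp / sm) ** 2 * noise_sd(n_ref_minus, model) ** 2)
    z = (abs_m - abs_p) * sp / den
    z[(Xm == 0) & (Xp == 0)] = 0.0
    zmed = np.median(z, axis=0)
    cols = minus_counts.columns if isinstance(minus_counts, pd.DataFrame) else None
    return pd.Series(zmed, index=cols)


def n_nonzero_asvs(minus_counts, plus_counts) -> int:
    """Number of ASVs with any nonzero count across the pair's samples."""
    tot = np.asarray(minus_counts).sum(axis=0) + np.asarray(plus_counts).sum(axis=0)
    return int(np.sum(tot > 0))


def call_enriched(z_by_condition: dict, zcrit_by_condition: dict,
                  regime_by_condition: dict,
                  nn_z: pd.Series | None = None,
                  nn_z_crit: float | None = None) -> dict[str, EnrichmentCall]:
    """Aggregate per-condition calls into per-regime enriched ASV sets.

    Per condition, enriched = {ASV : z > z_crit}; per regime, the union over
    that regime's conditions; NNresponders (enriched in the no-nitrate
    contrast at its own critical value) are removed from each union.
    """
    nn = set()
    if nn_z is not None:
        if nn_z_crit is None:
            nn_z_crit = critical_z(n_asv=2500)
        nn = set(nn_z.index[nn_z > nn_z_crit])
    out: dict[str, EnrichmentCall] = {}
    for regime in sorted(set(regime_by_condition.values())):
        conds = [c for c, r in regime_by_condition.items() if r == regime]
        union: set = set()
        zfs, crits = {}, {}
        for c in conds:
            z = z_by_condition[c]
            crit = zcrit_by_condition[c]
            union |= set(z.index[z > crit])
            zfs[c] = z
            crits[c] = crit
        out[regime] = EnrichmentCall(
            regime=regime,
            enriched=union - nn,
            nn_responders=union & nn,
            z=pd.DataFrame(zfs) if zfs else None,
            z_crit=crits,
        )
    return out
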