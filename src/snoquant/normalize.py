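"""Reference-gel selection and per-gel bias ("gain factor") normalization.

Gel-to-gel differences in loading, labeling and imaging act as a single
multiplicative bias on all spot volumes of a gel.  Under the assumption
that most spots do not change across the experiment, the log spot-ratios
of a gel against a common reference scatter around a mean that captures
exactly that bias; the gain factor is the multiplier that recentres this
mean log-ratio at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gelset import GelSet

__all__ = ["BiasFactor", "select_reference_gel", "compute_bias_factor", "normalize_gelset"]


@dataclass(frozen=True)
class BiasFactor:
    """Multiplicative gain applied to one gel's spot volumes."""

    gel_id: str
    gain: float

    def __post_init__(self):
        if not np.isfinite(self.gain) or self.gain <= 0:
            raise ValidationError(f"gain for gel {self.gel_id!r} must be positive and finite")


def select_reference_gel(gelset: GelSet) -> str:
    """Pick the gel that best represents the experiment.

    Criteria, in order: greatest number of nonzero spot volumes; then the
    highest median Spearman correlation of log-volumes with all other
    gels; remaining ties broken by lexicographic gel id.
    """
    if not gelset.gel_ids:
        raise ValidationError("cannot select a reference gel from an empty gel set")
    vols = gelset.volumes
    counts = (vols > 0).sum(axis=0)
    best = counts.max()
    candidates = sorted(counts.index[counts == best])
    if len(candidates) == 1 or len(gelset.gel_ids) == 1:
        return candidates[0]

    logv = np.log(vols.where(vols > 0))
    med_corr = {}
    if not logv.isna().any().any():
        # complete data: one rank transform + correlation matrix
        ranks = stats.rankdata(logv.to_numpy(), axis=0)
        corr = np.corrcoef(ranks, rowvar=False)
        np.fill_diagonal(corr, np.nan)
        med = pd.Series(np.nanmedian(corr, axis=0), index=vols.columns)
        med_corr = {gel: med[gel] for gel in candidates}
    else:
        for gel in candidates:
            corrs = []
            for other in vols.columns:
                if other == gel:
                    continue
                pair = pd.concat([logv[gel], logv[other]], axis=1).dropna()
                if len(pair) < 3:
                    continue
                rho = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
                if np.isfinite(rho):
                    corrs.append(rho)
            med_corr[gel] = np.median(corrs) if corrs else -np.inf
    # max correlation; candidates are sorted, so ties fall to the
    # lexicographically first gel id
    best_gel, best_val = candidates[0], med_corr[candidates[0]]
    for gel in candidates[1:]:
        if med_corr[gel] > best_val:
            best_gel, best_val = gel, med_corr[gel]
    return best_gel


def compute_bias_factor(
    gel: pd.Series, reference: pd.Series, gel_id: str = "", trim: float = 0.0
) -> BiasFactor:
    """Gain factor that zeroes a gel's mean log-ratio to the reference.

    ``gain = exp(-mean(ln(gel / reference)))`` over spots positive in both
    vectors.  ``trim`` trims that fraction from each tail of the log-ratio
    distribution before averaging (0 = plain mean).
    """
    if not 0.0 <= trim < 0.5:
        raise ValidationError("trim must lie in [0, 0.5)")
    g = np.asarray(gel, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.shape != r.shape:
        raise ValidationError("gel and reference vectors must be aligned")
    ok = (g > 0) & (r > 0)
    if ok.sum() < 3:
        raise ValidationError(
            f"gel {gel_id!r}: fewer than 3 spots positive in both gel and reference"
        )
    logr = np.log(g[ok] / r[ok])
    mean = stats.trim_mean(logr, trim) if trim > 0 else logr.mean()
    return BiasFactor(gel_id=gel_id, gain=float(np.exp(-mean)))


def normalize_gelset(gelset: GelSet, trim: float = 0.0) -> GelSet:
    """Scale every gel by its bias factor against the selected reference.

    Returns a new, normalized :class:`GelSet` with the reference gel id and
    per-gel gain factors recorded.  After normalization the mean log-ratio
    of every gel to the reference is zero (to floating tolerance).
    """
    if gelset.normalized:
        raise ValidationError("gel set is already normalized")
    ref_id = select_reference_gel(gelset)
    ref = gelset.volumes[ref_id]
    gains = {}
    for gel_id in gelset.gel_ids:
        gains[gel_id] = compute_bias_factor(
            gelset.volumes[gel_id], ref, gel_id=gel_id, trim=trim
        ).gain
    gains = pd.Series(gains, name="gain")
    out = GelSet(
        gelset.volumes * gains,
        gelset.gel_meta,
    )
    out.normalized = True
    out.reference_gel = ref_id
    out.gain_factors = gains
    return out
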