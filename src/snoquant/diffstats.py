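"""Spot-wise differential statistics and selection.

Statistics follow the standard 2D-GE differential workflow: volumes are
log2-transformed, each spot is summarised per group (mean, SD, CoV),
groups are compared with Welch's unequal-variance t-test, p-values are
corrected across spots with the Benjamini–Hochberg step-up procedure, and
spots are selected by a joint fold-change and significance threshold.
Selected spots are partitioned into a Venn classification: changed in
abundance only, in S-NO level only, or in both.

Two named significance presets are provided:

``discovery``
    |fold| >= 1.5 and BH-adjusted p < 0.05 — the screen used to nominate
    spots for identification.
``mars_input``
    |fold| >= 1.5 and BH-adjusted p < 0.001 — the stringent screen used
    to pick classifier input features.

The module exposes both the low-level operations (:func:`spot_stats`,
:func:`welch_t`, :func:`bh_adjust`, :func:`select_spots`,
:func:`venn_classify`) and a model object, :class:`DifferentialModel`,
whose :meth:`~DifferentialModel.fit` returns a
:class:`DifferentialResults` with the per-spot table, Venn counts and a
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .gelset import GelSet
from .normalize import normalize_gelset
from .ror import call_sno_direction, compute_ror, ror_table

__all__ = [
    "PRESETS",
    "spot_stats",
    "welch_t",
    "bh_adjust",
    "select_spots",
    "venn_classify",
    "DifferentialModel",
    "DifferentialResults",
]

PRESETS = {
    "discovery": {"fold_threshold": 1.5, "alpha": 0.05, "use_adjusted": True},
    "mars_input": {"fold_threshold": 1.5, "alpha": 0.001, "use_adjusted": True},
}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def spot_stats(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and CoV = SD/|mean| of one spot's values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValidationError("spot_stats requires >= 2 finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cov = sd / abs(mean) if mean != 0 else np.inf
    return mean, sd, cov


def _welch_arrays(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorised Welch t, Welch–Satterthwaite df and two-sided p."""
    se2_a = var_a / n_a
    se2_b = var_b / n_b
    denom2 = se2_a + se2_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(denom2)
        df = denom2**2 / (se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # zero pooled variance: equal means -> p = 1; unequal -> p -> 0
    zero_var = denom2 == 0
    if np.any(zero_var):
        equal = zero_var & (mean_a == mean_b)
        unequal = zero_var & ~equal
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        if np.any(unequal):
            warnings.warn("zero variance with unequal means: p set to 0")
            p = np.where(unequal, 0.0, p)
            t = np.where(unequal, np.sign(mean_a - mean_b) * np.inf, t)
        df = np.where(zero_var, n_a + n_b - 2.0, df)
    return t, df, p


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test between two samples.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("welch_t requires >= 2 values per group")
    t, df, p = _welch_arrays(
        a.mean(), a.var(ddof=1), len(a), b.mean(), b.var(ddof=1), len(b)
    )
    return float(t), float(df), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    The input order is preserved; NaN entries are excluded from the
    multiplicity count and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def select_spots(
    stats: pd.DataFrame,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    fold_col: str = "fold",
    p_col: str = "p",
    q_col: str = "q",
) -> pd.Series:
    """Boolean mask of spots passing |fold| >= threshold and p (or q) < alpha."""
    if fold_threshold < 1:
        raise ValidationError("fold_threshold must be >= 1")
    pv = stats[q_col] if use_adjusted else stats[p_col]
    return (stats[fold_col].abs() >= fold_threshold) & (pv < alpha)


def venn_classify(abundance_selected: set, sno_selected: set) -> dict[str, int]:
    """Counts of spots changed in both, abundance only, or S-NO only."""
    a, s = set(abundance_selected), set(sno_selected)
    return {
        "both": len(a & s),
        "abundance_only": len(a - s),
        "sno_only": len(s - a),
    }


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class DifferentialModel:
    """Dual-channel differential abundance / S-NO model for a gel set.

    Parameters
    ----------
    gelset : GelSet
        Input gel set; normalized automatically on ``fit`` if needed.
    preset : str, optional
        Named threshold preset (``"discovery"`` or ``"mars_input"``);
        individual keyword arguments override preset entries.
    fold_threshold, alpha, use_adjusted :
        Selection rule: |fold| >= ``fold_threshold`` and (BH-adjusted if
        ``use_adjusted``) p < ``alpha``.
    """

    def __init__(
        self,
        gelset: GelSet,
        preset: str = "discovery",
        fold_threshold: float | None = None,
        alpha: float | None = None,
        use_adjusted: bool | None = None,
    ):
        if preset not in PRESETS:
            raise ValidationError(f"unknown preset {preset!r}; use one of {sorted(PRESETS)}")
        params = dict(PRESETS[preset])
        if fold_threshold is not None:
            params["fold_threshold"] = fold_threshold
        if alpha is not None:
            params["alpha"] = alpha
        if use_adjusted is not None:
            params["use_adjusted"] = use_adjusted
        self.gelset = gelset
        self.preset = preset
        self.fold_threshold = params["fold_threshold"]
        self.alpha = params["alpha"]
        self.use_adjusted = params["use_adjusted"]

    @classmethod
    def from_tsv(cls, volumes_path, meta_path, **kwargs) -> "DifferentialModel":
        from .gelset import read_gelset

        return cls(read_gelset(volumes_path, meta_path), **kwargs)

    # -- helpers -------------------------------------------------------
    def _channel_stats(self, gelset: GelSet, channel: str) -> pd.DataFrame:
        """Per-spot log2 group summaries and Welch test for one channel."""
        out = {}
        grp_arrays = {}
        for group in ("NH", "HF"):
            gels = gelset.gels(group=group, channel=channel)
            vols = gelset.volumes[gels].to_numpy()
            with np.errstate(divide="ignore"):
                logv = np.where(vols > 0, np.log2(np.where(vols > 0, vols, 1.0)), np.nan)
            n = np.isfinite(logv).sum(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(logv, axis=1)
                var = np.nanvar(logv, axis=1, ddof=1)
                raw_mean = np.nanmean(np.where(vols > 0, vols, np.nan), axis=1)
                raw_sd = np.nanstd(np.where(vols > 0, vols, np.nan), axis=1, ddof=1)
            grp_arrays[group] = (mean, var, n)
            out[f"log2_mean_{group}"] = mean
            out[f"log2_sd_{group}"] = np.sqrt(var)
            out[f"cov_{group}"] = raw_sd / np.abs(raw_mean)
        (m_hf, v_hf, n_hf), (m_nh, v_nh, n_nh) = grp_arrays["HF"], grp_arrays["NH"]
        valid = (n_hf >= 2) & (n_nh >= 2)
        t = np.full(len(m_hf), np.nan)
        df = np.full(len(m_hf), np.nan)
        p = np.full(len(m_hf), np.nan)
        if valid.any():
            t[valid], df[valid], p[valid] = _welch_arrays(
                m_hf[valid], v_hf[valid], n_hf[valid],
                m_nh[valid], v_nh[valid], n_nh[valid],
            )
        out["welch_t"] = t
        out["welch_df"] = df
        out["p"] = np.where(valid, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
        out["q"] = bh_adjust(out["p"])
        return pd.DataFrame(out, index=gelset.spot_ids)

    # -- fitting -------------------------------------------------------
    def fit(self) -> "DifferentialResults":
        gelset = self.gelset
        if not gelset.normalized:
            gelset = normalize_gelset(gelset)

        abundance = self._channel_stats(gelset, "Asc+").add_suffix("_abundance")
        sno = self._channel_stats(gelset, "Asc-").add_suffix("_sno")
        rors = ror_table(gelset, threshold=self.fold_threshold).set_index("spot_id")

        table = pd.concat([abundance, sno, rors], axis=1)
        table.index.name = "spot_id"

        sig_ab = select_spots(
            table.assign(fold=table["delta_abundance"]),
            self.fold_threshold, self.alpha, self.use_adjusted,
            p_col="p_abundance", q_col="q_abundance",
        ) & table["delta_abundance"].notna()
        sig_sno = select_spots(
            table.assign(fold=table["ror"]),
            self.fold_threshold, self.alpha, self.use_adjusted,
            p_col="p_sno", q_col="q_sno",
        ) & table["ror"].notna()
        table["significant_abundance"] = sig_ab
        table["significant_sno"] = sig_sno
        table["abundance_direction"] = np.select(
            [sig_ab & (table["delta_abundance"] > 0), sig_ab & (table["delta_abundance"] < 0)],
            ["up", "down"], default="",
        )
        table["venn_category"] = np.select(
            [sig_ab & sig_sno, sig_ab & ~sig_sno, ~sig_ab & sig_sno],
            ["both", "abundance_only", "sno_only"], default="neither",
        )

        venn = venn_classify(set(table.index[sig_ab]), set(table.index[sig_sno]))
        return DifferentialResults(
            model=self,
            table=table.reset_index(),
            venn=venn,
            reference_gel=gelset.reference_gel,
            gain_factors=gelset.gain_factors,
            normalized_gelset=gelset,
        )


@dataclass
class DifferentialResults:
    """Fitted per-spot differential statistics.

    Attributes
    ----------
    table : DataFrame
        One row per spot: log2 group means/SDs, raw-scale CoVs, Welch
        t/df/p and BH q per channel, abundance fold, S-NO channel fold,
        RoR, direction calls, significance flags and Venn category.
    venn : dict
        Counts of ``both`` / ``abundance_only`` / ``sno_only`` spots.
    """

    model: DifferentialModel
    table: pd.DataFrame
    venn: dict[str, int]
    reference_gel: str | None
    gain_factors: pd.Series | None = field(repr=False, default=None)
    normalized_gelset: GelSet | None = field(repr=False, default=None)

    @property
    def abundance_selected(self) -> set[str]:
        t = self.table
        return set(t.loc[t["significant_abundance"], "spot_id"])

    @property
    def sno_selected(self) -> set[str]:
        t = self.table
        return set(t.loc[t["significant_sno"], "spot_id"])

    def summary(self) -> str:
        t = self.table
        m = self.model
        n_ab = int(t["significant_abundance"].sum())
        n_up = int((t["abundance_direction"] == "up").sum())
        n_down = int((t["abundance_direction"] == "down").sum())
        n_sno = int(t["significant_sno"].sum())
        sig_sno = t.loc[t["significant_sno"]]
        n_low = int((sig_sno["ror"] < 0).sum())   # low RoR = increased S-NO
        n_high = int((sig_sno["ror"] > 0).sum())  # high RoR = decreased S-NO
        lines = [
            "Dual-channel differential analysis",
            "==================================",
            f"preset: {m.preset}  |fold| >= {m.fold_threshold}, "
            f"{'BH q' if m.use_adjusted else 'raw p'} < {m.alpha}",
            f"spots tested: {len(t)}   reference gel: {self.reference_gel}",
            f"differentially abundant: {n_ab} ({n_up} up / {n_down} down)",
            f"differentially S-NO modified: {n_sno} "
            f"({n_low} low RoR / {n_high} high RoR)",
            "venn: both={both} abundance_only={abundance_only} "
            "sno_only={sno_only}".format(**self.venn),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
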