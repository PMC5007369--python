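"""The ratio-of-ratios (RoR) statistic for S-nitrosylation quantification.

The dual-channel design measures each subject's proteome twice: the Asc+
channel (all thiols reduced) reports protein abundance, and the Asc-
channel (S-NO preserved) reports abundance *minus* the dye signal lost to
S-nitrosylated cysteines.  Comparing HF to NH groups per channel gives

    delta_abundance = Asc+ HF / Asc+ NH
    delta_sno       = Asc- HF / Asc- NH

and their ratio, the ratio of ratios

    RoR = delta_sno / delta_abundance

isolates the S-NO change from the abundance change.  Because S-NO
modification quenches the thiol-directed fluorescence, a *negative* RoR
(in the signed fold convention) means S-NO levels *increased*, and a
positive RoR means they decreased.

Group ratios are ratios of geometric means (means of log2 volumes,
back-transformed), composing exactly with the log-scale statistics used
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .folds import fold_to_linear, linear_to_fold
from .gelset import GelSet

__all__ = [
    "RoRRecord",
    "group_ratio",
    "compute_ror",
    "call_sno_direction",
    "ror_table",
    "load_table_fixture",
    "verify_table_fixture",
]

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class RoRRecord:
    """Per-spot abundance change, S-NO channel change, RoR and direction call."""

    spot_id: str
    delta_abundance: float  # fold, Asc+ HF/NH
    delta_sno: float  # fold, Asc- HF/NH
    ror: float  # fold, delta_sno / delta_abundance
    sno_call: str


def _geom_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if len(pos) == 0:
        return np.nan
    return float(2.0 ** np.mean(np.log2(pos)))


def group_ratio(gelset: GelSet, spot_id: str, channel: str) -> float:
    """HF/NH fold change of a spot's normalized volume in one channel.

    The group summary is the geometric mean of normalized volumes (mean of
    log2 volumes, back-transformed).  Returns a signed fold value.
    """
    if not gelset.normalized:
        raise ValidationError("group_ratio requires a normalized gel set")
    hf = gelset.volumes.loc[spot_id, gelset.gels(group="HF", channel=channel)]
    nh = gelset.volumes.loc[spot_id, gelset.gels(group="NH", channel=channel)]
    if len(hf) < 2 or len(nh) < 2:
        raise ValidationError(f"channel {channel!r}: need >= 2 gels per group")
    m_hf, m_nh = _geom_mean(hf.to_numpy()), _geom_mean(nh.to_numpy())
    if not np.isfinite(m_hf) or not np.isfinite(m_nh) or m_nh == 0:
        raise ValidationError(f"spot {spot_id!r}: undefined group ratio (zero group mean)")
    return linear_to_fold(m_hf / m_nh)


def compute_ror(delta_sno: float, delta_abundance: float) -> float:
    """RoR = delta_sno / delta_abundance, computed on the linear scale."""
    return linear_to_fold(fold_to_linear(delta_sno) / fold_to_linear(delta_abundance))


def call_sno_direction(ror: float, threshold: float = 1.5) -> str:
    """Direction of the S-NO change implied by a RoR fold value.

    Quenching inverts the sign: RoR <= -threshold means S-NO increased,
    RoR >= +threshold means S-NO decreased, anything between is unchanged.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    if ror <= -threshold:
        return INCREASED
    if ror >= threshold:
        return DECREASED
    return UNCHANGED


def ror_table(gelset: GelSet, threshold: float = 1.5) -> pd.DataFrame:
    """Per-spot RoR table for a normalized gel set.

    Columns: spot_id, delta_abundance, delta_sno, ror, sno_call.  Spots
    with an undefined ratio in either channel (all-zero group) are
    reported with NA folds and an ``unchanged`` call.
    """
    if not gelset.normalized:
        raise ValidationError("ror_table requires a normalized gel set")

    def channel_log2_means(channel):
        means = {}
        for group in ("NH", "HF"):
            gels = gelset.gels(group=group, channel=channel)
            if len(gels) < 2:
                raise ValidationError(f"channel {channel!r}: need >= 2 gels per group")
            vols = gelset.volumes[gels].to_numpy()
            logv = np.where(vols > 0, np.log2(np.where(vols > 0, vols, 1.0)), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means[group] = np.nanmean(logv, axis=1)
        return means["HF"] - means["NH"]  # log2 ratio of geometric means

    log2_da = channel_log2_means("Asc+")
    log2_ds = channel_log2_means("Asc-")
    lin_da, lin_ds = 2.0**log2_da, 2.0**log2_ds
    ok = np.isfinite(lin_da) & np.isfinite(lin_ds)

    da = np.where(ok, np.where(lin_da >= 1, lin_da, -1.0 / lin_da), np.nan)
    ds = np.where(ok, np.where(lin_ds >= 1, lin_ds, -1.0 / lin_ds), np.nan)
    lin_ror = lin_ds / lin_da
    ror = np.where(ok, np.where(lin_ror >= 1, lin_ror, -1.0 / lin_ror), np.nan)
    call = np.select(
        [ok & (ror <= -threshold), ok & (ror >= threshold)],
        [INCREASED, DECREASED],
        default=UNCHANGED,
    )
    return pd.DataFrame(
        {
            "spot_id": gelset.spot_ids,
            "delta_abundance": da,
            "delta_sno": ds,
            "ror": ror,
            "sno_call": call,
        }
    )


# ---------------------------------------------------------------------------
# packaged spot-table fixture
# ---------------------------------------------------------------------------

def load_table_fixture() -> pd.DataFrame:
    """Load the packaged 2D-GE spot table (147 identified spots).

    Columns include the printed per-spot pI, molecular weight, protein and
    gene annotation, the Asc-/Asc+ channel ratios for each group
    (``delta_sno_NH``, ``delta_sno_HF``), the abundance fold
    (``abundance_HF_vs_NH``) and the printed RoR (``ror_HF_vs_NH``), all
    in the signed fold convention rounded to two decimals.
    """
    with resources.files("snoquant.data").joinpath("spot_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"spot_id": str})


def _fold_interval(f: float, half: float = 0.005) -> tuple[float, float]:
    """Interval of underlying fold values consistent with a printed fold.

    A printed fold is rounded to two decimals, so the underlying value
    lies within +/-0.005 — clipped to the valid fold domain |f| >= 1
    (a printed 1.00 can only come from folds in [1, 1.005]).
    """
    lo, hi = f - half, f + half
    if f >= 1:
        lo = max(1.0, lo)
    else:
        hi = min(-1.0, hi)
    return lo, hi


def verify_table_fixture(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every fixture row's RoR from its printed inputs.

    For each row, the printed S-NO channel fold (HF column) and abundance
    fold are each treated as intervals induced by two-decimal rounding;
    the RoR interval they imply is widened by the output's own +/-0.005
    rounding, and the printed RoR must fall inside.  Returns a report
    with the recomputed RoR, the admissible interval and a pass flag per
    row.
    """
    if fixture is None:
        fixture = load_table_fixture()
    required = {"spot_id", "delta_sno_HF", "abundance_HF_vs_NH", "ror_HF_vs_NH"}
    missing = required - set(fixture.columns)
    if missing:
        raise ValidationError(f"fixture missing columns: {sorted(missing)}")

    rows = []
    for _, row in fixture.iterrows():
        spot = row["spot_id"]
        try:
            ds = float(row["delta_sno_HF"])
            da = float(row["abundance_HF_vs_NH"])
            printed = float(row["ror_HF_vs_NH"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed fixture row for spot {spot!r}") from exc
        recomputed = compute_ror(ds, da)
        ds_lo, ds_hi = _fold_interval(ds)
        da_lo, da_hi = _fold_interval(da)
        lo = compute_ror(ds_lo, da_hi) - 0.005
        hi = compute_ror(ds_hi, da_lo) + 0.005
        rows.append((spot, ds, da, printed, recomputed, lo, hi, lo <= printed <= hi))
    return pd.DataFrame(
        rows,
        columns=[
            "spot_id", "delta_sno", "delta_abundance", "printed_ror",
            "recomputed_ror", "interval_lo", "interval_hi", "passed",
        ],
    )
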