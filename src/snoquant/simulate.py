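"""Synthetic dual-channel gel sets with known ground truth.

The generator emulates the split-sample saturation-labeling design: each
subject's lysate is divided into an ascorbate-reduced fraction (Asc+, all
cysteine thiols dye-reactive, fluorescence tracks protein abundance) and a
neocuproine-stabilised fraction (Asc-, S-nitrosylated thiols blocked, so
fluorescence is quenched in proportion to S-NO occupancy).  Each fraction
runs on its own gel, so a study with ``n`` subjects per group yields
``4 n`` gels: 2 groups (NH, HF) x 2 channels (Asc+, Asc-).

Generative model, per spot ``s`` and subject ``j`` of group ``g``::

    latent+  = mu_s * A_{g,s} * u_j            (biology, shared by channels)
    latent-  = latent+ * (1 - q_{g,s})         (linear fluorescence quenching)
    observed = latent * b_gel * eps            (gel bias x technical noise)

where ``mu_s`` is a baseline intensity drawn log-uniformly over three
orders of magnitude, ``A_{g,s}`` a planted abundance fold (1 for unaffected
spots), ``q_{g,s}`` the S-NO occupancy of the spot's cysteines,
``u_j`` a per-subject log-normal biological factor, ``b_gel`` a per-gel
log-normal bias, and ``eps`` mean-1 log-normal technical noise whose
coefficient of variation is ``technical_cov`` (sigma^2 = ln(1 + CoV^2)).

All randomness flows through one ``numpy`` generator seeded from
``config.seed``; identical configs give bit-identical gel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .gelset import GelSet

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_gelset", "dye_stoichiometry"]

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


def _cov_to_sigma(cov: float) -> float:
    # log-normal: CoV^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cov * cov)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic gel-set generator.

    Defaults mirror the study design the generator emulates: 30 subjects
    per group, 635 detected spots, ~9% technical CoV, abundance effects
    around 2-fold, and S-NO occupancy shifts of 0.3 on a 0.2 baseline.
    """

    n_subjects_per_group: int = 30
    n_spots: int = 635
    frac_abundance_diff: float = 0.15
    frac_sno_diff: float = 0.17
    abundance_effect_fold: float = 2.0
    sno_quench_base: float = 0.2
    sno_quench_effect: float = 0.3
    bias_log_sd: float = 0.2
    technical_cov: float = 0.09
    biological_cov: float = 0.15
    missing_frac: float = 0.0
    seed: int = 0
    # explicit affected-spot indices; override the frac_* counts when given
    abundance_spots: tuple[int, ...] | None = field(default=None)
    sno_spots: tuple[int, ...] | None = field(default=None)

    def __post_init__(self):
        def fail(name, why):
            raise ValidationError(f"SyntheticConfig.{name}: {why}")

        if self.n_subjects_per_group < 2:
            fail("n_subjects_per_group", "must be >= 2")
        if self.n_spots < 1:
            fail("n_spots", "must be >= 1")
        for name in ("frac_abundance_diff", "frac_sno_diff", "missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                fail(name, "must lie in [0, 1]")
        if self.abundance_effect_fold <= 0:
            fail("abundance_effect_fold", "must be positive")
        if not 0.0 <= self.sno_quench_base < 1.0:
            fail("sno_quench_base", "must lie in [0, 1)")
        if self.sno_quench_base + abs(self.sno_quench_effect) >= 1.0:
            fail("sno_quench_effect", "base + |effect| must be < 1")
        if self.technical_cov <= 0:
            fail("technical_cov", "must be > 0")
        if self.biological_cov < 0:
            fail("biological_cov", "must be >= 0")
        if self.bias_log_sd < 0:
            fail("bias_log_sd", "must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load from a flat key-value (YAML mapping) file; unknown keys rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("abundance_spots", "sno_spots"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Per-spot ground truth of a simulated gel set."""

    table: pd.DataFrame  # spot_id, true_abundance_fold, sno_direction, quench_NH, quench_HF

    @property
    def abundance_spots(self) -> set[str]:
        t = self.table
        return set(t.loc[t["true_abundance_fold"] != 1.0, "spot_id"])

    @property
    def sno_spots(self) -> set[str]:
        t = self.table
        return set(t.loc[t["sno_direction"] != UNCHANGED, "spot_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _affected_indices(rng, n_spots, frac, explicit):
    if explicit is not None:
        idx = np.asarray(explicit, dtype=int)
        if len(idx) and (idx.min() < 0 or idx.max() >= n_spots):
            raise ValidationError("explicit spot indices out of range")
        return np.sort(idx)
    k = int(round(frac * n_spots))
    return np.sort(rng.choice(n_spots, size=k, replace=False))


def simulate_gelset(config: SyntheticConfig) -> tuple[GelSet, SyntheticTruth]:
    """Simulate a two-group, two-channel gel set with known truth.

    Returns the (un-normalized) :class:`GelSet` and the
    :class:`SyntheticTruth` describing which spots carry planted abundance
    or S-NO effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_spots
    nspg = config.n_subjects_per_group

    ab_idx = _affected_indices(rng, n, config.frac_abundance_diff, config.abundance_spots)
    sno_idx = _affected_indices(rng, n, config.frac_sno_diff, config.sno_spots)

    spot_ids = np.array([f"s{i + 1:04d}" for i in range(n)])

    # planted abundance folds: alternate up/down among affected spots
    ab_factor_hf = np.ones(n)
    true_fold = np.ones(n)
    f = config.abundance_effect_fold
    f_hi = max(f, 1.0 / f)  # linear >= 1 form
    for rank, i in enumerate(ab_idx):
        lin = f_hi if rank % 2 == 0 else 1.0 / f_hi
        ab_factor_hf[i] = lin
        true_fold[i] = lin if lin >= 1 else -1.0 / lin

    # S-NO occupancies: affected spots alternate direction; a "decreased"
    # spot carries the elevated occupancy in the NH group instead, so the
    # shift magnitude is the same either way and stays within [0, 1)
    base = config.sno_quench_base
    q_nh = np.full(n, base)
    q_hf = q_nh.copy()
    eff = config.sno_quench_effect
    direction = np.full(n, UNCHANGED, dtype=object)
    for rank, i in enumerate(sno_idx):
        delta = eff if rank % 2 == 0 else -eff
        if delta > 0:
            q_hf[i] = base + delta
            direction[i] = INCREASED
        elif delta < 0:
            q_nh[i] = base - delta
            direction[i] = DECREASED

    # baseline spot intensity over >= 3 orders of magnitude
    mu = 10.0 ** rng.uniform(4.0, 7.0, size=n)

    sig_bio = _cov_to_sigma(config.biological_cov) if config.biological_cov > 0 else 0.0
    sig_tech = _cov_to_sigma(config.technical_cov)

    groups, channels = ("NH", "HF"), ("Asc+", "Asc-")
    gel_ids, meta_rows = [], []
    cols = {}
    for group in groups:
        q = q_nh if group == "NH" else q_hf
        abf = np.ones(n) if group == "NH" else ab_factor_hf
        for j in range(nspg):
            subject = f"{group}{j + 1:02d}"
            u = np.exp(rng.normal(-0.5 * sig_bio**2, sig_bio)) if sig_bio > 0 else 1.0
            latent_plus = mu * abf * u
            for channel in channels:
                latent = latent_plus if channel == "Asc+" else latent_plus * (1.0 - q)
                b = np.exp(rng.normal(0.0, config.bias_log_sd)) if config.bias_log_sd > 0 else 1.0
                eps = np.exp(rng.normal(-0.5 * sig_tech**2, sig_tech, size=n))
                gel_id = f"{subject}_{channel}"
                gel_ids.append(gel_id)
                cols[gel_id] = latent * b * eps
                meta_rows.append((gel_id, subject, group, channel))

    volumes = pd.DataFrame(cols, index=spot_ids)
    if config.missing_frac > 0:
        mask = rng.random(volumes.shape) < config.missing_frac
        volumes = volumes.where(~mask, 0.0)

    meta = pd.DataFrame(
        meta_rows, columns=["gel_id", "subject", "group", "channel"]
    ).set_index("gel_id")

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "spot_id": spot_ids,
                "true_abundance_fold": true_fold,
                "sno_direction": direction,
                "quench_NH": q_nh,
                "quench_HF": q_hf,
            }
        )
    )
    return GelSet(volumes, meta), truth


def dye_stoichiometry(
    protein_mass_ug: float,
    cys_density_pmol_per_ug: float,
    dye_excess: float,
    reaction_volume_ul: float,
    quench_excess: float,
) -> tuple[float, float]:
    """Saturation-labeling stoichiometry for thiol-directed dye and quencher.

    Computes the dye concentration needed to label ``protein_mass_ug`` of
    protein with ``cys_density_pmol_per_ug`` reactive cysteines at
    ``dye_excess``-fold molar excess over thiol in ``reaction_volume_ul``,
    and the 2-mercaptoethanol quencher concentration at ``quench_excess``
    fold over dye.  Returns ``(dye, quencher)`` in umol/mL.
    """
    vals = (protein_mass_ug, cys_density_pmol_per_ug, dye_excess,
            reaction_volume_ul, quench_excess)
    names = ("protein_mass_ug", "cys_density_pmol_per_ug", "dye_excess",
             "reaction_volume_ul", "quench_excess")
    for name, v in zip(names, vals):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"dye_stoichiometry: {name} must be positive")
    # pmol -> umol and uL -> mL cancel to a single factor of 1e-3
    thiol_pmol = protein_mass_ug * cys_density_pmol_per_ug
    dye_conc = thiol_pmol * dye_excess / reaction_volume_ul * 1e-3
    return dye_conc, dye_conc * quench_excess
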