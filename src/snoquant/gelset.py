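"""The GelSet container: a spot-volume matrix with per-gel annotations.

A gel set holds the fluorescence volume of every detected spot on every
gel of an experiment, together with the metadata that gives each gel its
place in the design: which subject it came from, which group the subject
belongs to (NH = normal healthy, HF = heart failure), and which labeling
channel it carries (Asc+ = ascorbate-reduced, all thiols dye-reactive;
Asc- = neocuproine-stabilised, S-nitrosylated thiols unreactive).

Volumes are stored as a pandas DataFrame with spot ids as the index and
gel ids as columns; metadata is a DataFrame indexed by gel id.  Both are
read and written as tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("NH", "HF")
CHANNELS = ("Asc+", "Asc-")

META_COLUMNS = ("subject", "group", "channel")


@dataclass
class GelSet:
    """Spot-volume matrix (spots x gels) plus per-gel design metadata."""

    volumes: pd.DataFrame
    gel_meta: pd.DataFrame
    normalized: bool = False
    reference_gel: str | None = None
    gain_factors: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        self.volumes = self.volumes.astype(float)
        self.volumes.index = self.volumes.index.astype(str)
        self.volumes.index.name = "spot_id"
        self.volumes.columns = self.volumes.columns.astype(str)
        self.gel_meta = self.gel_meta.copy()
        self.gel_meta.index = self.gel_meta.index.astype(str)
        self.gel_meta.index.name = "gel_id"
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.volumes.shape[1] == 0:
            raise ValidationError("gel set contains no gels")
        if self.volumes.index.duplicated().any():
            dupes = self.volumes.index[self.volumes.index.duplicated()].tolist()
            raise ValidationError(f"duplicate spot ids: {dupes}")
        if self.volumes.columns.duplicated().any():
            dupes = self.volumes.columns[self.volumes.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gel ids: {dupes}")
        missing_meta = set(self.volumes.columns) - set(self.gel_meta.index)
        if missing_meta:
            raise ValidationError(f"gels without metadata: {sorted(missing_meta)}")
        extra_meta = set(self.gel_meta.index) - set(self.volumes.columns)
        if extra_meta:
            raise ValidationError(
                f"metadata rows for gels absent from volumes: {sorted(extra_meta)}"
            )
        for col in META_COLUMNS:
            if col not in self.gel_meta.columns:
                raise ValidationError(f"gel metadata missing column '{col}'")
        bad_group = set(self.gel_meta["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_channel = set(self.gel_meta["channel"]) - set(CHANNELS)
        if bad_channel:
            raise ValidationError(f"unknown channel labels: {sorted(bad_channel)}")
        vals = self.volumes.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("volumes contain non-finite values")
        if (vals < 0).any():
            spot, gel = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative volume at spot {self.volumes.index[spot]!r}, "
                f"gel {self.volumes.columns[gel]!r}"
            )
        # align metadata row order with volume columns
        self.gel_meta = self.gel_meta.loc[list(self.volumes.columns)]

    # -- convenience selectors -----------------------------------------
    @property
    def spot_ids(self) -> list[str]:
        return list(self.volumes.index)

    @property
    def gel_ids(self) -> list[str]:
        return list(self.volumes.columns)

    def gels(self, group: str | None = None, channel: str | None = None) -> list[str]:
        """Gel ids matching the given group and/or channel."""
        mask = pd.Series(True, index=self.gel_meta.index)
        if group is not None:
            mask &= self.gel_meta["group"] == group
        if channel is not None:
            mask &= self.gel_meta["channel"] == channel
        return list(self.gel_meta.index[mask])

    def subset(self, gel_ids: list[str]) -> "GelSet":
        return GelSet(
            self.volumes[gel_ids],
            self.gel_meta.loc[gel_ids],
            normalized=self.normalized,
            reference_gel=self.reference_gel,
        )

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, volumes_path, meta_path) -> None:
        vol = self.volumes.copy()
        vol.index.name = "spot_id"
        vol.to_csv(volumes_path, sep="\t")
        meta = self.gel_meta.copy()
        meta.index.name = "gel_id"
        meta.to_csv(meta_path, sep="\t")


def read_gelset(volumes_path, meta_path) -> GelSet:
    """Read a gel set from its volumes/metadata TSV pair.

    Raises :class:`ValidationError` with the offending row or column named
    for missing columns, unknown group/channel tokens, duplicate ids, or
    non-numeric / negative volumes.
    """
    vol = pd.read_csv(volumes_path, sep="\t", dtype={0: str})
    if vol.columns[0] != "spot_id":
        raise ValidationError(
            f"volumes file must start with a 'spot_id' column, got {vol.columns[0]!r}"
        )
    vol = vol.set_index("spot_id")
    for gel in vol.columns:
        coerced = pd.to_numeric(vol[gel], errors="coerce")
        bad = coerced.isna() & vol[gel].notna()
        if bad.any():
            spot = vol.index[bad][0]
            raise ValidationError(
                f"non-numeric volume at spot {spot!r}, gel {gel!r}"
            )
        vol[gel] = coerced
    if vol.isna().any().any():
        raise ValidationError("volumes file contains missing values")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "gel_id" not in meta.columns:
        raise ValidationError("gel metadata must have a 'gel_id' column")
    if meta["gel_id"].duplicated().any():
        raise ValidationError("duplicate gel_id rows in metadata")
    meta = meta.set_index("gel_id")
    return GelSet(vol, meta)
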