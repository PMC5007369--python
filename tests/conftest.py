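import numpy as np
import pandas as pd
import pytest

from snoquant.gelset import GelSet


def make_gelset(volumes: dict[str, list[float]], spot_ids=None, normalized=False) -> GelSet:
    """Build a GelSet from a {gel_id: volumes} dict.

    Gel ids must follow '<GROUP><nn>_<channel>' (e.g. 'NH01_Asc+'); group,
    subject and channel metadata are derived from the id.
    """
    vols = pd.DataFrame(volumes)
    if spot_ids is not None:
        vols.index = spot_ids
    else:
        vols.index = [f"s{i + 1:03d}" for i in range(len(vols))]
    meta = []
    for gel_id in vols.columns:
        subject, channel = gel_id.rsplit("_", 1)
        group = subject[:2]
        meta.append((gel_id, subject, group, channel))
    meta = pd.DataFrame(
        meta, columns=["gel_id", "subject", "group", "channel"]
    ).set_index("gel_id")
    gs = GelSet(vols, meta)
    gs.normalized = normalized
    return gs


@pytest.fixture
def paired_gelset():
    """4 subjects x 2 groups x 2 channels, 6 spots, exactly bias-free."""
    rng = np.random.default_rng(42)
    base = 10.0 ** rng.uniform(4, 6, size=6)
    cols = {}
    for group in ("NH", "HF"):
        for j in (1, 2):
            for channel in ("Asc+", "Asc-"):
                noise = rng.lognormal(0, 0.05, size=6)
                scale = 1.0 if channel == "Asc+" else 0.8
                cols[f"{group}{j:02d}_{channel}"] = base * scale * noise
    return make_gelset(cols)
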