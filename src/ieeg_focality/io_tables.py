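"""Round-tripping clip feature tensors through long-format tables.

The on-disk interchange format for clip features is a long CSV with columns
``patient, clip, channel, band, measure, value`` (pairs spelled
``chanA|chanB``) plus a ``roi`` column carrying the channel's ROI (for pairs,
the anode-side channel's ROI; the pair's ROI pair is reconstructed from the
member channels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_processing import BAND_NAMES, ClipFeatureTensor


def features_from_long_table(table: pd.DataFrame) -> dict[str, ClipFeatureTensor]:
    """Rebuild per-patient :class:`ClipFeatureTensor` objects from a long table."""
    required = {"patient", "clip", "channel", "band", "measure", "value", "roi"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    out: dict[str, ClipFeatureTensor] = {}
    for pid, sub in table.groupby("patient"):
        power = sub[sub["measure"] == "power"]
        coh = sub[sub["measure"] == "coherence"]
        channels = sorted(power["channel"].unique().tolist())
        ch_index = {c: i for i, c in enumerate(channels)}
        clips = sorted(sub["clip"].unique().tolist())
        clip_index = {k: i for i, k in enumerate(clips)}
        roi_map = (
            power.drop_duplicates("channel").set_index("channel")["roi"].to_dict()
        )
        rel = np.full((len(clips), len(channels), len(BAND_NAMES)), np.nan)
        b_index = {b: i for i, b in enumerate(BAND_NAMES)}
        for row in power.itertuples(index=False):
            rel[clip_index[row.clip], ch_index[row.channel], b_index[row.band]] = row.value
        pair_names = sorted(coh["channel"].unique().tolist())
        pairs = np.array(
            [[ch_index[p.split("|")[0]], ch_index[p.split("|")[1]]] for p in pair_names],
            dtype=int,
        ).reshape(-1, 2)
        p_index = {p: i for i, p in enumerate(pair_names)}
        msc = np.full((len(clips), len(pair_names), len(BAND_NAMES)), np.nan)
        for row in coh.itertuples(index=False):
            msc[clip_index[row.clip], p_index[row.channel], b_index[row.band]] = row.value
        out[str(pid)] = ClipFeatureTensor(
            channels=channels,
            rois=[roi_map[c] for c in channels],
            rel_power=rel,
            coherence=msc,
            pairs=pairs,
        )
    return out
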