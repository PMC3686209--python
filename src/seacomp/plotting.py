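"""Optional matplotlib views: ecotype box panels and genome tracks.

These are convenience renderings of tables the pipeline already writes; no
statistic is computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_ecotype_boxes(profiles: pd.DataFrame, w: float = 1.5, axes=None):
    """One box-and-whisker panel per sea, one box per ecotype axis."""
    import matplotlib.pyplot as plt

    meta = ("cluster_id", "sea", "n_reads", "kl_from_mean", "prescreen_outlier", "outlier")
    eco_cols = [c for c in profiles.columns if c not in meta]
    seas = list(dict.fromkeys(profiles["sea"]))
    if axes is None:
        _, axes = plt.subplots(1, len(seas), figsize=(3 * len(seas), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, sea in zip(axes, seas):
        grp = profiles[(profiles["sea"] == sea) & (profiles["n_reads"] > 0)]
        ax.boxplot([grp[c].to_numpy(dtype=float) for c in eco_cols],
                   tick_labels=eco_cols, whis=w)
        ax.set_title(sea)
        ax.set_ylabel("ecotype frequency")
    return axes


def plot_genome_track(track, ax=None):
    """Entropy along the reference, differential clusters marked, HVRs shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    rec = track.records
    for r in rec.itertuples():
        color = "black" if r.differential else "0.7"
        ax.plot([r.start, r.end], [r.entropy, r.entropy], color=color, lw=2)
    for h in track.hvrs.itertuples():
        ax.axvspan(h.start, h.end, color="tab:orange", alpha=0.2)
    ax.set_xlabel(f"position on {track.reference_genome_id} (bp)")
    ax.set_ylabel("entropy (nats)")
    return ax
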