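"""Optional matplotlib views of the linkage diagnostics."""

from __future__ import annotations

from typing import Mapping, Sequence

from .linkage import SIZE_BINS


def plot_common_pgc_curve(curves: Mapping[str, Sequence[int]], ax=None):
    """Common-code count vs number of incorporated runs, one line per mode."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(range(1, len(curve) + 1), curve, marker=".", label=label)
    ax.set_xlabel("runs incorporated")
    ax.set_ylabel("common PGCs")
    ax.legend()
    return ax


def plot_group_size_histogram(hist: Mapping[str, int], ax=None):
    """Bar chart of group counts per size bin (1, 2, 3–5, >5)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(list(SIZE_BINS), [hist.get(b, 0) for b in SIZE_BINS])
    ax.set_xlabel("group size")
    ax.set_ylabel("groups")
    return ax


def plot_change_log(log, ax=None):
    """New identities, new groups and mergers per processed run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = log.to_frame()
    x = range(1, len(frame) + 1)
    ax.plot(x, frame["new_accessions"], lw=2, label="new identities")
    ax.plot(x, frame["new_groups"], lw=1, label="new groups")
    ax.plot(x, frame["mergers"], ls=":", label="mergers")
    ax.set_xlabel("runs processed")
    ax.legend()
    return ax
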