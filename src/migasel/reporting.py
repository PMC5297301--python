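"""Post-hoc analyses of a feature-selection result.

Given a best chromosome and the feature index map, tallies the selected
features by family (AR vs DWT), channel (C3 vs C4) and wavelet level, and
profiles how many selected features fall in each sliding-window position
- the per-window profile localizes, in trial time, where the
discriminative information lives.  Also tabulates GA convergence
histories and flags the generation at which the maximum fitness reached
its final plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SelectionSummary:
    total_selected: int
    by_family: dict[str, int]
    by_channel: dict[str, int]
    by_dwt_level: dict[int, int]
    per_window: np.ndarray  # selected-feature count per window position

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "", self.total_selected)]
        rows += [("family", k, v) for k, v in sorted(self.by_family.items())]
        rows += [("channel", k, v) for k, v in sorted(self.by_channel.items())]
        rows += [("dwt_level", f"L{k}", v)
                 for k, v in sorted(self.by_dwt_level.items())]
        return pd.DataFrame(rows, columns=["group", "key", "count"])


def summarize_selection(chrom: np.ndarray, index_map: pd.DataFrame) -> SelectionSummary:
    """Decode every selected column of ``chrom`` through the index map.

    The count identities (family counts sum to the total, channel counts
    sum to the total, per-window counts sum to the total) hold exactly by
    construction.
    """
    chrom = np.asarray(chrom).astype(bool)
    if chrom.size != len(index_map):
        raise ValueError(
            f"chromosome of {chrom.size} genes but index map of {len(index_map)} rows")
    sel = index_map[chrom]
    n_windows = int(index_map["window_index"].max()) + 1 if len(index_map) else 0
    per_window = np.zeros(n_windows, dtype=int)
    counts = sel["window_index"].value_counts()
    per_window[counts.index.to_numpy()] = counts.to_numpy()
    by_level = {int(k): int(v)
                for k, v in sel["dwt_level"].dropna().value_counts().items()}
    return SelectionSummary(
        total_selected=int(chrom.sum()),
        by_family={k: int(v) for k, v in sel["family"].value_counts().items()},
        by_channel={k: int(v) for k, v in sel["channel"].value_counts().items()},
        by_dwt_level=by_level,
        per_window=per_window,
    )


def per_window_table(summary: SelectionSummary) -> pd.DataFrame:
    return pd.DataFrame({
        "window_index": np.arange(summary.per_window.size),
        "selected_features": summary.per_window,
    })


def convergence_table(history, check_elitist: bool = False) -> pd.DataFrame:
    """Tabulate (generation, mean_fitness, max_fitness) and flag the plateau.

    The ``at_plateau`` column marks every generation from the first at
    which the max fitness equals its final value.  With
    ``check_elitist=True`` a decreasing max column raises, since an
    elitist run guarantees monotonicity.
    """
    hist = list(history)
    if not hist:
        raise ValueError("empty history")
    means = np.array([h[0] for h in hist], dtype=float)
    maxes = np.array([h[1] for h in hist], dtype=float)
    if check_elitist and np.any(np.diff(maxes) < 0):
        raise ValueError("max fitness decreased: history is not from an elitist run")
    plateau_gen = int(np.argmax(maxes == maxes[-1])) + 1  # 1-based generation
    gens = np.arange(1, len(hist) + 1)
    return pd.DataFrame({
        "generation": gens,
        "mean_fitness": means,
        "max_fitness": maxes,
        "at_plateau": gens >= plateau_gen,
    })


def plot_convergence(table: pd.DataFrame, path) -> None:
    """Optional convergence plot (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["generation"], table["mean_fitness"], label="mean fitness")
    ax.plot(table["generation"], table["max_fitness"], label="max fitness")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness (testing accuracy)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
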