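"""Optional figures: tornado diagram, CE-plane scatter, acceptability curve."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .econ import TornadoEntry


def tornado_plot(entries: Sequence[TornadoEntry], base_icer: float, path,
                 top: int = 10) -> None:
    ent = [e for e in entries if np.isfinite(e.range) and e.range > 0][:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(ent) + 1.5))
    for i, e in enumerate(ent):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(ent)), [e.parameter for e in ent])
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(samples: pd.DataFrame, wtp: float, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples["delta_qaly"], samples["delta_cost"], s=3, alpha=0.25)
    xs = np.array(ax.get_xlim())
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP = ${wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(ceac_df: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["wtp"], ceac_df["probability_cost_effective"])
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
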