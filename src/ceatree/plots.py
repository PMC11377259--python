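"""Optional figures: tornado diagram, acceptability curve, CE-plane scatter."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import CEACPoint, PSADraw, TornadoEntry  # noqa: E402


def tornado_plot(
    entries: Sequence[TornadoEntry],
    base_icer: float,
    path: Union[str, Path],
    max_bars: int = 15,
) -> Path:
    """Horizontal tornado bars around the base-case (EV) ICER; entries with an
    undefined ICER at a range end are drawn over the visible span."""
    shown = list(entries[:max_bars])[::-1]
    finite = [
        v for e in entries[:max_bars] for v in (e.icer_at_low, e.icer_at_high)
        if isinstance(v, float)
    ] + [base_icer]
    lo_lim, hi_lim = min(finite), max(finite)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo = e.icer_at_low if isinstance(e.icer_at_low, float) else lo_lim
        hi = e.icer_at_high if isinstance(e.icer_at_high, float) else hi_lim
        left, right = min(lo, hi), max(lo, hi)
        ax.barh(i, right - left, left=left, color="#4878CF", height=0.6)
    ax.axvline(base_icer, color="black", lw=1, ls="--",
               label=f"EV = {base_icer:,.2f}")
    ax.set_yticks(range(len(shown)), [e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER (CNY/QALD)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ceac_plot(points: Sequence[CEACPoint], path: Union[str, Path]) -> Path:
    wtp = [p.wtp for p in points]
    prob = [p.probability_ce for p in points]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(wtp, prob, label="treatment")
    ax.plot(wtp, [1 - p for p in prob], label="comparator", ls="--")
    ax.set_xlabel("Willingness-to-pay (CNY/QALD)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ce_plane_plot(
    draws: Sequence[PSADraw],
    path: Union[str, Path],
    wtp: Optional[float] = None,
) -> Path:
    """Incremental (ΔE, ΔC) scatter with the WTP ray ΔC = wtp·ΔE."""
    de = [d.delta_effect for d in draws]
    dc = [d.delta_cost for d in draws]
    fig, ax = plt.subplots(figsize=(6.5, 5))
    ax.scatter(de, dc, s=8, alpha=0.4, edgecolors="none")
    ax.axhline(0, color="gray", lw=0.8)
    ax.axvline(0, color="gray", lw=0.8)
    if wtp is not None and de:
        xs = [min(de), max(de)]
        ax.plot(xs, [wtp * x for x in xs], color="crimson", lw=1,
                label=f"WTP = {wtp:,.2f} CNY/QALD")
        ax.legend(fontsize=8)
    ax.set_xlabel("Incremental effect (QALD)")
    ax.set_ylabel("Incremental cost (CNY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
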