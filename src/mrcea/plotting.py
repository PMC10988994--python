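"""Minimal plotting helpers: forest plots for effect estimates.

NMB histograms live on :meth:`mrcea.cea.CEAResult.plot_nmb`.
"""

from __future__ import annotations

from typing import Sequence


def plot_forest(estimates: Sequence, labels: Sequence[str] | None = None,
                ax=None, unit: str = ""):
    """Forest plot of estimates carrying ``beta``/``ci95`` (MR results) or
    ``wald_ratio``/``se_ratio`` (per-variant estimates)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * len(estimates) + 1))
    ys = range(len(estimates))
    for y, est in zip(ys, estimates):
        if hasattr(est, "wald_ratio"):
            beta = est.wald_ratio
            lo, hi = beta - 1.96 * est.se_ratio, beta + 1.96 * est.se_ratio
        else:
            beta, (lo, hi) = est.beta, est.ci95
        ax.plot([lo, hi], [y, y], color="#333333", lw=1.2)
        ax.plot([beta], [y], "s", color="#4878a8")
    if labels is None:
        labels = [getattr(e, "variant", getattr(e, "outcome_label", str(i)))
                  for i, e in enumerate(estimates)]
    ax.set_yticks(list(ys), labels)
    ax.axvline(0.0, color="r", ls="--", lw=0.8)
    ax.set_xlabel(f"effect estimate {unit}".strip())
    ax.invert_yaxis()
    return ax
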