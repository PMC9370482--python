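"""Optional matplotlib views of the cohort report (threshold sweep, per-group
activation rates and depth-resolved histograms)."""

from __future__ import annotations

from typing import Optional

from .cohort_statistics import CohortReport, SweepCurve


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_sweep(sweep: SweepCurve, selected_rt: Optional[float] = None, ax=None):
    """AR(R_T) per group with the selected threshold marked."""
    ax = _get_ax(ax)
    for group, curve in sweep.ar_percent.items():
        ax.plot(sweep.grid, curve, label=group)
    if selected_rt is not None:
        ax.axvline(selected_rt, color="k", linestyle="--", label=f"$R_T$ = {selected_rt:g}")
    ax.set_xlabel("activation threshold $R_T$")
    ax.set_ylabel("AR (%)")
    ax.legend()
    return ax


def plot_activation_rates(report: CohortReport, ax=None):
    """Bar chart of per-group AR at the selected threshold."""
    ax = _get_ax(ax)
    groups = list(report.ar_percent)
    ax.bar(groups, [report.ar_percent[g] for g in groups])
    ax.set_ylabel(f"AR (%) at $R_T$ = {report.selected_rt:g}")
    return ax


def plot_ar_delta(report: CohortReport, ax=None, width_um: float = 0.35):
    """Grouped histogram of AR_delta over indentation depth."""
    ax = _get_ax(ax)
    groups = [g for g in report.ar_delta if any(k != "unassigned" for k in report.ar_delta[g])]
    for i, g in enumerate(groups):
        hist = {k: v for k, v in report.ar_delta[g].items() if k != "unassigned"}
        deltas = sorted(float(k) for k in hist)
        ax.bar(
            [d + (i - (len(groups) - 1) / 2) * width_um for d in deltas],
            [hist[f"{d:.2f}"] for d in deltas],
            width=width_um,
            label=g,
        )
    ax.set_xlabel(r"indentation depth $\delta$ ($\mu$m)")
    ax.set_ylabel(r"AR$_\delta$ (%)")
    ax.legend()
    return ax
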