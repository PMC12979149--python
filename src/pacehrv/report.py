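"""Text tables and figures for a completed study run.

Tables mirror the standard reporting layout for this protocol: a
positive-delta table (metric x contrast, count and percent), a
median-(IQR)-per-period table with contrast p-values, and one Bland-Altman
agreement table per metric (pair, bias, SD of differences, %bias).  Medians
are formatted as ``815 (759–957)``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import stats as chs

METRIC_TITLES = {
    "rmssd": "RMSSD (ms)",
    "delta_pp": "dPP (ms)",
    "median_cl": "SR CL (ms)",
    "snrt": "SNRT (ms)",
    "csnrt": "cSNRT (ms)",
    "wp_rate": "Wenckebach point (bpm)",
}


def fmt_median_iqr(median: float, q1: float, q3: float, decimals: int = 1) -> str:
    """Format ``815.0, (759, 957)`` as ``"815 (759–957)"``."""
    def num(x: float) -> str:
        if np.isnan(x):
            return "NA"
        if decimals == 0 or float(x).is_integer():
            return str(int(round(x)))
        return f"{x:.{decimals}f}"

    return f"{num(median)} ({num(q1)}–{num(q3)})"


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_tables(summary: dict) -> str:
    """Render the full text report from a run summary."""
    if summary.get("n_patients", 0) == 0:
        raise ValueError("empty summary: no patients")
    lines: list[str] = []
    n = summary["n_patients"]
    lines.append(f"Cohort: n = {n} patients; Bonferroni threshold "
                 f"p < {summary['bonferroni_threshold']:g} (two prespecified contrasts)")
    lines.append("")

    lines.append("== Pacing-induced positive deltas (post - pre > 0) ==")
    lines.append(f"{'Comparison':<12}{'Metric':<14}{'n with d>0':<12}{'%':<8}")
    for metric, block in summary["metrics"].items():
        for pair, pd_block in block["positive_delta"].items():
            comp = pair.replace("-", " vs. ")
            lines.append(f"{comp:<12}{METRIC_TITLES.get(metric, metric):<14}"
                         f"{pd_block['count']:<12}{pd_block['percent']:.0f}")
    lines.append("")

    lines.append("== Median (IQR) per period ==")
    for metric, block in summary["metrics"].items():
        dec = 1 if metric == "rmssd" else 0
        tests = block["tests"]["contrasts"]
        lines.append(f"-- {METRIC_TITLES.get(metric, metric)} --")
        for period in chs.PERIODS:
            cell = block["periods"][period]
            lines.append(f"  period {period}: "
                         + fmt_median_iqr(cell["median"], cell["q1"], cell["q3"], dec))
        lines.append(f"  Friedman p = {_fmt_p(block['tests']['friedman']['p'])}; "
                     f"A-B p = {_fmt_p(tests['A-B']['p'])}, "
                     f"C-D p = {_fmt_p(tests['C-D']['p'])}, "
                     f"A-C p = {_fmt_p(tests['A-C']['p'])}, "
                     f"B-D p = {_fmt_p(tests['B-D']['p'])}")
    lines.append("")

    for metric, block in summary["metrics"].items():
        lines.append(f"== Bland-Altman agreement for {METRIC_TITLES.get(metric, metric)} ==")
        lines.append(f"{'Periods':<10}{'Bias [ms]':<12}{'SD [ms]':<10}{'Bias (%)':<10}")
        for pair, ba in block["bland_altman"].items():
            comp = pair.replace("-", " vs. ")
            lines.append(f"{comp:<10}{ba['bias']:<+12.2f}{ba['sd_diff']:<10.2f}"
                         f"{ba['pct_bias']:<+10.2f}")
        lines.append("")

    if summary.get("ep_params"):
        lines.append("== Electrophysiological parameters (post-pacing) ==")
        for metric, block in summary["ep_params"].items():
            b, d = block["B"], block["D"]
            lines.append(f"{METRIC_TITLES.get(metric, metric)}: "
                         f"B {fmt_median_iqr(b['median'], b['q1'], b['q3'], 0)}, "
                         f"D {fmt_median_iqr(d['median'], d['q1'], d['q3'], 0)}, "
                         f"p (B vs. D) = {_fmt_p(block['wilcoxon_B_D']['p'])}")
        lines.append("")
    return "\n".join(lines) + "\n"


def save_plots(frame: pd.DataFrame, plot_dir: str) -> list[str]:
    """Bland-Altman (2x2 pairs) and SODP scatter plots per HRV metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plot_dir, exist_ok=True)
    paths: list[str] = []
    pairs = (("A", "B"), ("C", "D"), ("A", "C"), ("B", "D"))
    for metric in ("rmssd", "delta_pp"):
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        for ax, pair in zip(axes.ravel(), pairs):
            x, y = chs._pair_vectors(frame, metric, pair)
            mean, diff = (x + y) / 2.0, x - y
            ax.scatter(mean, diff, s=18, alpha=0.7)
            ax.axhline(float(np.mean(diff)), color="firebrick", lw=1.2,
                       label=f"bias {np.mean(diff):+.1f} ms")
            ax.axhline(0.0, color="grey", lw=0.8, ls=":")
            ax.set_title(f"{metric} {pair[0]} vs {pair[1]}")
            ax.set_xlabel("pair mean (ms)")
            ax.set_ylabel(f"{pair[0]} - {pair[1]} (ms)")
            ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = os.path.join(plot_dir, f"bland_altman_{metric}.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)

        records, _, _ = chs.sodp(frame, metric)
        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        p1 = np.array([r.points[0] for r in records])
        p2 = np.array([r.points[1] for r in records])
        if p1.size:
            ax.scatter(p1[:, 0], p1[:, 1], s=20, alpha=0.7, label="(B-A, C-B)")
            ax.scatter(p2[:, 0], p2[:, 1], s=20, alpha=0.7, marker="s",
                       label="(C-B, D-C)")
        ax.axhline(0, color="grey", lw=0.8)
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel("$\\Delta_n$ (ms)")
        ax.set_ylabel("$\\Delta_{n+1}$ (ms)")
        ax.set_title(f"SODP: {metric}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = os.path.join(plot_dir, f"sodp_{metric}.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
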