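"""Figure/HTML report rendered from a finished pipeline run directory.

Plots are deterministic for fixed inputs (no timestamps or random ids in
the SVG output) so identical runs produce identical report files.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["make_report"]

plt.rcParams["svg.hashsalt"] = "chiprx"
_SVG_META = {"Date": None}


def _read_table(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", comment="#")


def _save(fig, path: Path) -> None:
    fig.savefig(path, format="svg", metadata=_SVG_META)
    plt.close(fig)


def make_report(run_dir: str | Path) -> Path:
    """Render SVG figures and an HTML index for a pipeline run.

    Sections whose input table is missing are skipped with a notice in the
    HTML, so partial runs still report what they have.
    """
    run = Path(run_dir)
    summary_path = run / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"{run} does not contain summary.json")
    with open(summary_path) as fh:
        summary = json.load(fh)
    figdir = run / "figures"
    figdir.mkdir(exist_ok=True)
    sections: list[str] = []
    params = f"config {summary['config_digest']}, " \
             f"{summary['normalization_mode'].upper()} units"

    # enhancer state fractions per condition
    fracs = summary.get("state_fractions", {})
    if fracs:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        conditions = list(fracs)
        bottoms = [0.0] * len(conditions)
        for state, color in (("active", "#d62728"), ("primed", "#bcbd22"),
                             ("poised", "#1f77b4")):
            vals = [fracs[c].get(state, 0.0) for c in conditions]
            ax.bar(conditions, vals, bottom=bottoms, label=state, color=color)
            bottoms = [b + v for b, v in zip(bottoms, vals)]
        ax.set_ylabel("fraction of enhancers")
        ax.set_title(f"Enhancer states ({params})", fontsize=8)
        ax.legend(fontsize=7)
        _save(fig, figdir / "enhancer_states.svg")
        sections.append("enhancer_states")

    # density boxsummaries
    for name, title in (
        ("h3k27ac_enhancer_density", "H3K27ac at common/unique/shuffled enhancers"),
        ("h3k36me2_peak_density", "H3K36me2 at common/unique/shuffled peaks"),
    ):
        df = _read_table(run / f"{name}.tsv")
        if df is None:
            sections.append(f"missing:{name}")
            continue
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.bar(df["group"], df["mean"], color="#888888")
        ax.set_ylabel("mean density")
        ax.set_title(f"{title}\n({params})", fontsize=8)
        _save(fig, figdir / f"{name}.svg")
        sections.append(name)

    # delta scatter with r annotation
    deltas = _read_table(run / "delta_records.tsv")
    if deltas is not None and len(deltas):
        corr = {c["y"]: c for c in summary.get("correlations", [])}
        for mark in sorted(deltas["mark"].unique()):
            if mark == "paired":
                continue
            sub = deltas[deltas["mark"] == mark]
            fig, ax = plt.subplots(figsize=(4, 3.6))
            ax.scatter(sub["occupancy"], sub["delta"], s=4, alpha=0.4,
                       color="#1f77b4")
            info = corr.get(f"delta_{mark}")
            if info:
                ax.set_title(
                    f"delta {mark} vs H3K36M occupancy  "
                    f"r={info['r']:.2f}, n={info['n']}\n({params})",
                    fontsize=8)
            ax.set_xlabel("H3K36M occupancy (density)")
            ax.set_ylabel(f"delta {mark}")
            _save(fig, figdir / f"delta_{mark}.svg")
            sections.append(f"delta_{mark}")
    else:
        sections.append("missing:delta_records")

    # inactivated-enhancer count bins vs expression change
    bins = _read_table(run / "inactivated_count_bins.tsv")
    if bins is not None and len(bins):
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.bar(bins["bin"].astype(str), bins["median_log2fc"], color="#2ca02c")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("inactivated enhancers per gene")
        ax.set_ylabel("median log2 fold-change")
        ax.set_title(f"Expression vs enhancer inactivation ({params})",
                     fontsize=8)
        _save(fig, figdir / "inactivated_bins.svg")
        sections.append("inactivated_bins")
    else:
        sections.append("missing:inactivated_count_bins")

    html = [
        "<html><head><title>chiprx report</title></head><body>",
        f"<h1>chiprx run report</h1><p>{params}</p>",
        f"<p>Inactivated: {summary.get('inactivated')} of "
        f"{summary.get('wt_active')} WT-active enhancers "
        f"({summary.get('inactivated_pct', float('nan')):.1f}%)</p>",
        f"<p>Convention: {summary.get('classification_convention')}</p>",
    ]
    for s in sections:
        if s.startswith("missing:"):
            html.append(f"<p><em>Section {s[8:]} skipped: input missing.</em></p>")
        else:
            html.append(f"<h2>{s}</h2><img src='figures/{s}.svg'/>")
    html.append("</body></html>")
    out = run / "report.html"
    out.write_text("\n".join(html))
    return out
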