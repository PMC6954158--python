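"""Study-level tables, tradeoff matrix and figures.

Turns the tidy metrics/fits tables of a complete study grid into:

* a resolution table (fitted FWHM mean +/- SD per preset per contrast
  level, three largest spheres pooled over scans),
* an SNR table (mean +/- SD per preset, pooled over contrast levels
  and scans),
* contrast-recovery-versus-diameter series (CRpeak and CRmax),
* a pairwise CRpeak/SNR tradeoff matrix,

all as deterministic CSV/JSON plus optional matplotlib figures.  The
builder is a pure function of its input tables: the same input yields
byte-identical CSV output.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stats import SMALL_SPHERES, TradeoffCell, classify_tradeoff

__all__ = ["ReportBundle", "build_reports", "save_reports"]

LARGE_SPHERES = ("37", "28", "22")


@dataclass
class ReportBundle:
    resolution_table: pd.DataFrame
    snr_table: pd.DataFrame
    cr_curves: pd.DataFrame
    tradeoff_matrix: pd.DataFrame
    metadata: dict


def _check_complete_grid(df: pd.DataFrame, what: str) -> None:
    presets = sorted(df["preset"].unique())
    sbrs = sorted(df["sbr"].unique())
    scans = sorted(df["scan"].unique())
    have = set(map(tuple, df[["preset", "sbr", "scan"]].drop_duplicates().to_numpy()))
    missing = [cell for cell in itertools.product(presets, sbrs, scans) if cell not in have]
    if missing:
        raise ValueError(f"{what} table is missing study cells: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))


def build_reports(
    metrics: pd.DataFrame,
    fits: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    large_spheres=LARGE_SPHERES,
    small_spheres=SMALL_SPHERES,
) -> ReportBundle:
    """Assemble all report tables from a complete study grid.

    ``pairs`` selects the tradeoff comparisons (method, comparator);
    by default every ordered pair of a penalized-likelihood preset
    (name starting with "Q.") against a conventional one.
    """
    _check_complete_grid(metrics, "metrics")
    _check_complete_grid(fits, "fits")

    f = fits[fits["sphere"].astype(str).isin(large_spheres)]
    resolution = (
        f.groupby(["preset", "sbr"])["fwhm"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values(["preset", "sbr"], kind="mergesort")
        .reset_index(drop=True)
    )

    snr_cells = metrics.groupby(["preset", "sbr", "scan"])["snr"].first().reset_index()
    snr_table = (
        snr_cells.groupby("preset")["snr"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values("preset", kind="mergesort")
        .reset_index(drop=True)
    )

    cr_curves = (
        metrics.groupby(["preset", "sbr", "sphere"])[["crpeak", "crmax"]]
        .mean()
        .reset_index()
        .sort_values(["preset", "sbr", "sphere"], kind="mergesort")
        .reset_index(drop=True)
    )

    preset_names = sorted(metrics["preset"].unique())
    if pairs is None:
        qclear = [p for p in preset_names if p.startswith("Q.")]
        conventional = [p for p in preset_names if not p.startswith("Q.")]
        pairs = [(a, b) for a in qclear for b in conventional]
    cells: list[TradeoffCell] = []
    for a, b in pairs:
        ma = metrics[metrics["preset"] == a]
        mb = metrics[metrics["preset"] == b]
        if ma.empty or mb.empty:
            raise ValueError(f"tradeoff pair ({a}, {b}) not present in the metrics table")
        cells.append(classify_tradeoff(ma, mb, small_spheres=small_spheres,
                                       method_a=a, method_b=b))
    tradeoff = pd.DataFrame(
        [{"method": c.method_a, "comparator": c.method_b,
          "crpeak": c.crpeak_verdict, "snr": c.snr_verdict} for c in cells]
    )

    metadata = {
        "large_spheres": list(large_spheres),
        "small_spheres": list(small_spheres),
        "snr_pairing": "sbr x scan",
        "fwhm_pairing": "scan x sphere (three largest spheres)",
        "n_presets": len(preset_names),
    }
    return ReportBundle(resolution_table=resolution, snr_table=snr_table,
                        cr_curves=cr_curves, tradeoff_matrix=tradeoff,
                        metadata=metadata)


def save_reports(bundle: ReportBundle, out_dir, make_plots: bool = True) -> dict[str, str]:
    """Write CSVs (+ JSON metadata, optional figures) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (
        ("resolution_table", bundle.resolution_table),
        ("snr_table", bundle.snr_table),
        ("cr_curves", bundle.cr_curves),
        ("tradeoff_matrix", bundle.tradeoff_matrix),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        written[name] = str(path)
    meta_path = out / "report_metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
    written["metadata"] = str(meta_path)
    if make_plots:
        written.update(_make_plots(bundle, out))
    return written


def _make_plots(bundle: ReportBundle, out: Path) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    # contrast recovery vs sphere diameter, one panel per contrast level
    cr = bundle.cr_curves.copy()
    cr["diameter"] = cr["sphere"].astype(int)
    sbrs = sorted(cr["sbr"].unique())
    for metric in ("crpeak", "crmax"):
        fig, axes = plt.subplots(1, len(sbrs), figsize=(4 * len(sbrs), 3.2),
                                 sharey=True, squeeze=False)
        for ax, sbr in zip(axes[0], sbrs):
            sub = cr[cr["sbr"] == sbr].sort_values("diameter")
            for preset, g in sub.groupby("preset"):
                ax.plot(g["diameter"], g[metric], marker="o", label=preset)
            ax.axhline(1.0, color="grey", lw=0.8, ls="--")
            ax.set_title(f"SBR {sbr}")
            ax.set_xlabel("sphere diameter [mm]")
        axes[0][0].set_ylabel(metric.upper())
        axes[0][-1].legend(fontsize=6)
        fig.tight_layout()
        path = out / f"{metric}_vs_diameter.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written[f"{metric}_plot"] = str(path)

    # tradeoff matrix
    tm = bundle.tradeoff_matrix
    if not tm.empty:
        color = {"higher": "#2ca02c", "equal": "#bbbbbb", "lower": "#d62728"}
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(tm) + 1))
        for row, (_, cell) in enumerate(tm.iterrows()):
            ax.barh(row, 1, left=0, color=color[cell["crpeak"]])
            ax.barh(row, 1, left=1.1, color=color[cell["snr"]])
            ax.text(-0.1, row, f'{cell["method"]} vs {cell["comparator"]}',
                    ha="right", va="center", fontsize=7)
        ax.set_xlim(-4, 2.2)
        ax.set_xticks([0.5, 1.6])
        ax.set_xticklabels(["CRpeak", "SNR"])
        ax.set_yticks([])
        ax.set_title("green: higher, grey: equal, red: lower (method vs comparator)",
                     fontsize=8)
        fig.tight_layout()
        path = out / "tradeoff_matrix.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written["tradeoff_plot"] = str(path)
    return written
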