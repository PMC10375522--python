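"""Figures and tables summarizing a refinement run.

Produces parameter-vs-time panels (linear time axis to 1 ps, then
logarithmic, the customary presentation for pump-probe series spanning
decades), data-vs-model comparison panels, and the kinetics summary as
CSV and Markdown.
"""

from __future__ import annotations

import csv
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import AnisoDataset
from .kinetics import KineticsResult
from .model import ForwardModel
from .refine import RefinementResult

__all__ = ["report"]

_SPLIT = 1.0  # ps; linear/log axis break


def _split_axes(fig, rect_pair):
    ax_lin, ax_log = rect_pair
    ax_log.set_xscale("log")
    ax_log.yaxis.set_visible(False)
    return ax_lin, ax_log


def _plot_split(axes, t, y, **kw):
    ax_lin, ax_log = axes
    early = t <= _SPLIT
    ax_lin.plot(t[early], y[early], **kw)
    kw.pop("label", None)
    ax_log.plot(t[~early], y[~early], **kw)


def _parameter_figure(result: RefinementResult, path: Path) -> None:
    t = result.t
    fig, axs = plt.subplots(
        2, 2, figsize=(9, 6), sharex="col",
        gridspec_kw={"width_ratios": [1, 2], "wspace": 0.04},
    )
    top = _split_axes(fig, axs[0])
    bot = _split_axes(fig, axs[1])
    for name, color in (("r12", "tab:red"), ("r23", "tab:blue")):
        _plot_split(top, t, result.column(name), color=color, marker=".", label=name)
    top[0].set_ylabel("distance (Å)")
    top[0].legend(loc="upper left", fontsize=8)
    for name, color in (
        ("A_iso", "k"), ("A_GP", "tab:green"), ("A_heat", "tab:orange")
    ):
        _plot_split(bot, t, result.column(name), color=color, marker=".", label=name)
    bot[0].set_ylabel("amplitude")
    bot[0].legend(loc="upper left", fontsize=8)
    for ax in (*top, *bot):
        ax.axvline(_SPLIT, color="0.8", lw=0.5)
    bot[0].set_xlabel("t (ps)")
    bot[1].set_xlabel("t (ps)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _fit_figure(
    result: RefinementResult, dataset: AnisoDataset, fm: ForwardModel, path: Path
) -> None:
    picks = np.unique(
        np.clip(
            [np.searchsorted(dataset.t, tv) for tv in (0.2, 0.5, 2.0, 50.0)],
            0, len(dataset.t) - 1,
        )
    )
    fig, axs = plt.subplots(
        len(picks), 2, figsize=(9, 2.2 * len(picks)), sharex=True, squeeze=False
    )
    for row, i in enumerate(picks):
        x = result.x[i]
        for col, (data, model, label) in enumerate(
            (
                (dataset.dS0[i], fm.iso_array(x), "ΔS₀"),
                (dataset.dS2[i], fm.aniso_array(x), "ΔS₂"),
            )
        ):
            ax = axs[row, col]
            ax.plot(dataset.q, data, "r.", ms=2.5, label="data")
            ax.plot(dataset.q, model, "k-", lw=1, label="model")
            ax.set_ylabel(f"{label} (e.u.)")
            ax.set_title(f"t = {dataset.t[i]:.2f} ps", fontsize=8)
            if row == 0 and col == 0:
                ax.legend(fontsize=7)
    for ax in axs[-1]:
        ax.set_xlabel("q (Å⁻¹)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _kinetics_tables(kin: KineticsResult, outdir: Path) -> None:
    rows = [(k, v) for k, v in kin.as_dict().items() if k != "flags"]
    with open(outdir / "kinetics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["quantity", "value"])
        for k, v in rows:
            w.writerow([k, f"{v:.6g}"])
    lines = [
        "| quantity | value |",
        "| --- | --- |",
        *[f"| {k} | {v:.4g} |" for k, v in rows],
    ]
    (outdir / "kinetics.md").write_text("\n".join(lines) + "\n")


def report(
    result: RefinementResult,
    kin: KineticsResult | None,
    dataset: AnisoDataset | None,
    fm: ForwardModel | None,
    outdir,
) -> list[Path]:
    """Write the standard figures and tables; returns the written paths."""
    if result is None or len(result.t) == 0:
        raise ValueError("empty refinement result; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "parameters_vs_time.png"
    _parameter_figure(result, p)
    written.append(p)
    if dataset is not None and fm is not None:
        p = outdir / "data_vs_model.png"
        _fit_figure(result, dataset, fm, p)
        written.append(p)
    if kin is not None:
        _kinetics_tables(kin, outdir)
        written.extend([outdir / "kinetics.csv", outdir / "kinetics.md"])
    return written
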