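"""Static renderings of a simulated cohort: trajectory spaghetti plots and
Kaplan–Meier overlays."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import Dataset
from .survstats import dataset_records

__all__ = ["spaghetti_plot", "km_plot"]


def _color_for(dataset: Dataset, key: str, levels: list) -> dict:
    custom = dataset.metadata.get("colormaps", {}).get(key)
    if isinstance(custom, dict):
        return {lv: custom.get(str(lv)) for lv in levels}
    if isinstance(custom, list) and len(custom) >= len(levels):
        return dict(zip(levels, custom))
    cmap = plt.get_cmap("tab10")
    return {lv: cmap(i % 10) for i, lv in enumerate(levels)}


def spaghetti_plot(
    dataset: Dataset,
    path: str | Path,
    color_by: Optional[str] = None,
    log_scale: bool = True,
) -> Path:
    """One line per subject through their non-missing measurements.

    ``color_by`` names a baseline covariate or ``"subgroup"`` (default).
    """
    key = color_by or "subgroup"
    smap = dataset.subject_map()
    if key != "subgroup":
        names = {c.name for c in dataset.covariate_specs}
        if key not in names:
            raise KeyError(
                f"unknown covariate {key!r}; available: {sorted(names)}"
            )

    def label(sid: str):
        s = smap[sid]
        return s.subgroup if key == "subgroup" else s.covariates.get(key)

    levels = sorted({label(s.id) for s in dataset.subjects}, key=str)
    colors = _color_for(dataset, key, levels)
    by_subject: dict[str, list] = {}
    for o in dataset.observations:
        if not o.missing and o.value is not None:
            by_subject.setdefault(o.subject_id, []).append((o.time, o.value))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    seen = set()
    for sid, pts in by_subject.items():
        pts.sort()
        lv = label(sid)
        ax.plot(
            [t for t, _ in pts],
            [max(v, 1e-12) if log_scale else v for _, v in pts],
            color=colors[lv],
            alpha=0.5,
            lw=0.9,
            label=str(lv) if lv not in seen else None,
        )
        seen.add(lv)
    lod = dataset.metadata.get("lod")
    if lod:
        ax.axhline(lod, ls="--", color="gray", lw=1, label="LoD")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel(f"time ({dataset.metadata.get('time_unit', 'time')})")
    ax.set_ylabel("MRD level")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def km_plot(
    dataset: Dataset,
    path: str | Path,
    group_by: str = "subgroup",
    endpoint: Optional[str] = None,
) -> Path:
    """Kaplan–Meier overlay by subgroup or by a baseline covariate."""
    from lifelines import KaplanMeierFitter

    records = dataset_records(dataset, endpoint=endpoint, group_by=group_by)
    groups = sorted({r.group for r in records})
    colors = _color_for(dataset, group_by, groups)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g in groups:
        sub = [r for r in records if r.group == g]
        kmf = KaplanMeierFitter()
        kmf.fit(
            np.array([r.time for r in sub]),
            event_observed=np.array([r.status for r in sub]),
            label=str(g),
        )
        kmf.plot_survival_function(ax=ax, ci_show=False, color=colors[g])
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"time ({dataset.metadata.get('time_unit', 'time')})")
    ax.set_ylabel("event-free probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
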