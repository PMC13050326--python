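"""Figure rendering: the safety-annotated ROC curve, the safety profile
curve, and the two-model comparison grid.

Every figure is written together with a machine-readable JSON sidecar
(same path, ``.json`` suffix) holding exactly the numbers plotted; the
figures are a view, never the source of truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; deterministic output
import matplotlib.pyplot as plt
import numpy as np

from .cohort import ScoredCohort, _jsonable
from .errors import UsageError
from .metrics import ThresholdTable, auc, gray_area, youden_theta
from .resampling import zone_concordance
from .zones import (
    SafetyPolicy,
    ZONE_GRAY,
    ZONE_RULE_IN,
    ZONE_RULE_OUT,
    make_partition,
)

__all__ = ["PlotSpec", "render_saroc", "render_safety_profile", "render_two_model_grid"]

_DEFAULT_COLORS = {
    ZONE_RULE_IN: "#c23b23",   # red family
    ZONE_RULE_OUT: "#2b6cb0",  # blue family
    ZONE_GRAY: "#9a9a9a",
}


@dataclass
class PlotSpec:
    """Rendering options shared by the figure functions."""

    alpha_levels: tuple = (1.0,)
    colors: dict = field(default_factory=lambda: dict(_DEFAULT_COLORS))
    dpi: int = 150

    def __post_init__(self):
        self.alpha_levels = tuple(sorted(self.alpha_levels))
        if len(self.alpha_levels) == 0:
            raise UsageError("at least one alpha level is required")
        if len(set(self.colors.values())) < len(self.colors):
            raise UsageError("zone colors must be distinct")


def _write_sidecar(path: Path, payload: dict) -> None:
    side = path.with_suffix(path.suffix + ".json")
    with open(side, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
        fh.write("\n")


def _zone_of(tau: float, boundaries) -> str:
    if tau >= boundaries.tau_plus:
        return ZONE_RULE_IN
    if tau < boundaries.tau_minus:
        return ZONE_RULE_OUT
    return ZONE_GRAY


def render_saroc(
    cohort: ScoredCohort,
    alpha_levels=(1.0,),
    path="saroc.png",
    spec: PlotSpec | None = None,
    theta: float | None = None,
) -> Path:
    """Safety-annotated ROC curve.

    The empirical ROC polyline is drawn once per safety level (nested
    levels offset by shade), each segment colored by the zone containing
    its threshold; the Γ_Area rectangle of each level is outlined in the
    top-left corner and the reference threshold θ (Youden by default) is
    marked. Sidecar: per-level boundaries, Γ, and the candidate→zone map.
    """
    spec = spec or PlotSpec(alpha_levels=tuple(alpha_levels))
    path = Path(path)
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    # ROC vertices ordered from (0,0) (high τ) to (1,1) (low τ)
    order = np.argsort(-table.candidates)
    fpr, tpr, cand = table.fpr[order], table.tpr[order], table.candidates[order]

    theta_val = youden_theta(cohort) if theta is None else theta
    fig, ax = plt.subplots(figsize=(5.2, 5.2))
    sidecar_levels = []
    n_levels = len(spec.alpha_levels)
    for rank, a in enumerate(sorted(spec.alpha_levels, reverse=True)):
        part = make_partition(cohort, SafetyPolicy.symmetric(a))
        b = part.boundaries
        shade = 1.0 - 0.45 * rank / max(n_levels - 1, 1)
        zones_per_vertex = [_zone_of(t, b) for t in cand]
        for k in range(len(cand) - 1):
            # segment k..k+1 corresponds to the lower-threshold endpoint
            z = zones_per_vertex[k + 1]
            ax.plot(
                fpr[k:k + 2], tpr[k:k + 2],
                color=spec.colors[z], alpha=shade, lw=2.0,
                solid_capstyle="round",
            )
        gamma = gray_area(cohort, b)
        # Γ rectangle: x ∈ [0, FPR(τ⁻)], y ∈ [TPR(τ⁺), 1]
        fpr_tm = np.count_nonzero(cohort.scores[cohort.labels == 0] >= b.tau_minus_raw) / cohort.n_neg
        tpr_tp = np.count_nonzero(cohort.scores[cohort.labels == 1] >= b.tau_plus_raw) / cohort.n_pos
        ax.add_patch(
            plt.Rectangle(
                (0, tpr_tp), fpr_tm, 1 - tpr_tp,
                facecolor=spec.colors[ZONE_GRAY], alpha=0.18, edgecolor="k",
                lw=0.6, linestyle="--",
            )
        )
        sidecar_levels.append(
            {
                "alpha": a,
                "boundaries": b.to_record(),
                "gamma_area": gamma,
                "gray_fraction": float(np.mean(part.assignment == ZONE_GRAY)),
                "candidate_zones": {
                    ("-inf" if np.isneginf(t) else "inf" if np.isposinf(t) else repr(float(t))): z
                    for t, z in zip(cand, zones_per_vertex)
                },
            }
        )
    from .metrics import roc_point_at

    pt = roc_point_at(cohort, theta_val)
    ax.plot([pt.fpr], [pt.tpr], "o", color="k", ms=7, mfc="none", mew=1.6,
            label=f"θ = {theta_val:g}")
    ax.plot([0, 1], [0, 1], color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(
        f"SA-ROC (AUC = {auc(cohort):.3f}; α = "
        + ", ".join(f"{a:g}" for a in spec.alpha_levels) + ")"
    )
    ax.legend(loc="lower right", fontsize=8)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    _write_sidecar(path, {"kind": "saroc", "auc": auc(cohort), "theta": theta_val,
                          "levels": sidecar_levels})
    return path


def render_safety_profile(profile, path="profile.png", spec: PlotSpec | None = None,
                          label: str | None = None, overlay=None) -> Path:
    """Two stacked panels: gray-zone fraction and Γ_Area versus the safety
    level. ``overlay`` accepts a second (profile, label) pair for model
    comparison. Sidecar: the profile rows verbatim."""
    spec = spec or PlotSpec()
    path = Path(path)
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(5.6, 5.2))
    profiles = [(profile, label or "model")]
    if overlay is not None:
        profiles.append(overlay)
    for prof, lab in profiles:
        rows = prof.rows
        ax1.plot(rows["alpha"], 100 * rows["gray_fraction"], lw=1.8, label=lab)
        ax2.plot(rows["alpha"], rows["gamma_area"], lw=1.8, label=lab)
    ax1.set_ylabel("Gray zone (% of cohort)")
    ax2.set_ylabel("Γ area")
    ax2.set_xlabel("Safety level α")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    payload = {"kind": "safety_profile",
               "profiles": [{"label": lab, **prof.to_record()} for prof, lab in profiles]}
    _write_sidecar(path, payload)
    return path


def render_two_model_grid(
    cohort_a: ScoredCohort,
    cohort_b: ScoredCohort,
    alpha: float = 1.0,
    path="grid.png",
    spec: PlotSpec | None = None,
) -> Path:
    """Per-case scatter of (score_A, score_B) over the joint safe-zone grid
    at a symmetric level α. Sidecar: the zone-concordance table."""
    spec = spec or PlotSpec(alpha_levels=(alpha,))
    path = Path(path)
    pa = make_partition(cohort_a, SafetyPolicy.symmetric(alpha))
    pb = make_partition(cohort_b, SafetyPolicy.symmetric(alpha))
    conc = zone_concordance(pa, pb)  # validates the case pairing

    order_b = {cid: k for k, cid in enumerate(cohort_b.case_ids)}
    align = np.array([order_b[cid] for cid in cohort_a.case_ids])
    xs, ys = cohort_a.scores, cohort_b.scores[align]

    fig, ax = plt.subplots(figsize=(5.4, 5.4))
    for b, t in ((pa.boundaries, "a"), (pb.boundaries, "b")):
        for tau in (b.tau_minus, b.tau_plus):
            if np.isfinite(tau):
                if t == "a":
                    ax.axvline(tau, color="0.4", lw=0.8, ls="--")
                else:
                    ax.axhline(tau, color="0.4", lw=0.8, ls="--")
    pos = cohort_a.labels == 1
    ax.scatter(xs[~pos], ys[~pos], s=12, c="#2b6cb0", alpha=0.55, label="negative")
    ax.scatter(xs[pos], ys[pos], s=12, c="#c23b23", alpha=0.55, label="positive")
    ax.set_xlabel("model A score")
    ax.set_ylabel("model B score")
    ax.set_title(f"Joint safe-zone grid (α = {alpha:g})")
    ax.legend(fontsize=8, loc="upper left")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    _write_sidecar(
        path,
        {
            "kind": "two_model_grid",
            "alpha": alpha,
            "boundaries_a": pa.boundaries.to_record(),
            "boundaries_b": pb.boundaries.to_record(),
            "concordance": {a: {b: int(conc.loc[a, b]) for b in conc.columns}
                            for a in conc.index},
        },
    )
    return path
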