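"""Optional plotting layer over the report TSVs (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import CohortTimeline, cohort_weekly_dynamics  # noqa: E402
from .model import TaxonomyMap  # noqa: E402
from .report import patient_plotu_profile  # noqa: E402


def plot_weekly_dynamics(timeline: CohortTimeline, glotu_ids: list[str],
                         tmap: TaxonomyMap, path) -> None:
    """Two-panel weekly dynamics: fraction of infants colonized per GLOTU
    and mean semi-quantitative score among the colonized (bars give the
    mean weekly maximum score, annotated with colonized counts)."""
    fig, (ax_frac, ax_score) = plt.subplots(
        2, 1, figsize=(7, 7), sharex=True)
    for glotu in glotu_ids:
        stats = cohort_weekly_dynamics(timeline, glotu, tmap)
        weeks = sorted(stats)
        ax_frac.plot(weeks, [stats[w].fraction_colonized for w in weeks],
                     marker="o", label=glotu)
        pts = [(w, stats[w].mean_score) for w in weeks
               if stats[w].mean_score is not None]
        if pts:
            ax_score.plot(*zip(*pts), marker="s", label=glotu)
    ax_frac.set_ylabel("fraction of sampled infants colonized")
    ax_frac.set_ylim(0, 1.05)
    ax_frac.legend(fontsize=8)
    ax_score.set_ylabel("mean weekly score (colonized)")
    ax_score.set_xlabel("week of life")
    ax_score.set_ylim(0, 3.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_patient_profiles(timeline: CohortTimeline, tmap: TaxonomyMap,
                          path) -> None:
    """Stacked per-patient PLOTU composition bars."""
    infants = timeline.infant_ids
    plotus = sorted({p for i in infants
                     for p in patient_plotu_profile(timeline, i, tmap)})
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(infants)), 4))
    bottoms = [0.0] * len(infants)
    for plotu in plotus:
        vals = [patient_plotu_profile(timeline, i, tmap).get(plotu, 0.0)
                for i in infants]
        ax.bar(infants, vals, bottom=bottoms, label=plotu)
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_ylabel("fraction of positive OTU occurrences")
    ax.legend(fontsize=7)
    ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
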