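"""In-memory convenience pipelines shared by scripts and tests."""

from __future__ import annotations

import numpy as np

from .io_model import EventPanel, build_panel, reconcile_reports
from .kinship_space import Pedigree, family_distances, family_relatedness
from .reciprocity_dynamics import class_curve, fit_null, sample_null
from .synthetic_data import SimParams, simulate_study


def simulate_and_build(params: SimParams):
    """Simulate a study and run it through observation and reconciliation.

    Returns (village, ground_truth, panel, relmat, distmat).
    """
    village, gt, true_events, records = simulate_study(params)
    events = reconcile_reports(records, seed=params.seed)
    panel = build_panel(village, records, events)
    relmat = family_relatedness(Pedigree(village.individuals), village)
    distmat = family_distances(village)
    return village, gt, panel, relmat, distmat


def reciprocity_analysis(panel: EventPanel, relmat, level: str,
                         classes=("all", "close_kin", "not_close_kin"),
                         n_null: int = 200, seed: int = 0,
                         lags=range(1, 11)):
    """Fit one null level, sample its ensemble, and build class curves."""
    null = fit_null(panel, relmat, level)
    ensemble = sample_null(null, panel.o, panel.guest_only, n_null, seed=seed)
    curves = {}
    for cls in classes:
        try:
            curves[cls] = class_curve(panel, ensemble, relmat, cls,
                                      lags=lags, null_level=level)
        except ValueError:
            curves[cls] = None
    return null, ensemble, curves


def panel_from_realization(panel: EventPanel, h: np.ndarray) -> EventPanel:
    """Wrap a simulated hosting tensor in the observed panel's window."""
    return EventPanel(family_ids=list(panel.family_ids),
                      h=np.asarray(h, np.uint8) & panel.o,
                      o=panel.o.copy(), guest_only=panel.guest_only.copy())
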