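"""End-to-end virtual multisite trial: simulate, fit, harmonize, compare.

A "virtual implementation" is a named fitting configuration standing in for
one site's analysis platform.  The default roster spans the two algorithm
families whose split drives inter-implementation ADC differences: two
log-linear implementations and two nonlinear-least-squares implementations
(the members of a family produce near-identical maps, as real same-family
platforms do, while the families diverge with noise level).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .concordance import ConcordanceReport, analyze
from .fitting import FitConfig, fit_volume
from .images import DWIStudy
from .roi import ROISet, apply_rois, make_tumor_roi, make_vial_rois, stats_to_rows
from .synth import (
    BREAST_B_VALUES_4,
    BREAST_SNR,
    PHANTOM_SNR,
    NoiseModel,
    add_noise,
    compute_trace,
    default_breast_spec,
    default_phantom_spec,
    make_breast,
    make_phantom,
    snr_sigma,
)

#: the default roster of virtual analysis implementations
DEFAULT_IMPLEMENTATIONS: dict[str, FitConfig] = {
    "AI-LL1": FitConfig(method="loglinear"),
    "AI-LL2": FitConfig(method="loglinear"),            # independent same-family port
    "AI-NLS1": FitConfig(method="nls"),
    "AI-NLS2": FitConfig(method="nls", nls_xtol=1e-12),
}


@dataclass
class SimulatedDataset:
    dataset_id: str
    study: DWIStudy          # noisy trace study, as sites would receive it
    rois: ROISet


def simulate_phantom_dataset(seed: int, snr: float = PHANTOM_SNR,
                             dataset_id: str = "Ph4b-01") -> SimulatedDataset:
    """One noisy trace phantom acquisition with its 13 vial ROIs."""
    spec = default_phantom_spec()
    study = make_phantom(spec)
    noisy = add_noise(study, NoiseModel("rician", snr_sigma(spec.s0, snr), seed))
    trace = compute_trace(noisy)
    return SimulatedDataset(dataset_id, trace, make_vial_rois(spec))


def simulate_breast_cohort(n_studies: int, seed: int, snr: float = BREAST_SNR,
                           b_values=BREAST_B_VALUES_4) -> list[SimulatedDataset]:
    """A cohort of virtual breast patients, one noisy trace study each."""
    out = []
    for k in range(n_studies):
        spec = default_breast_spec(seed=seed + 1000 * k, b_values=b_values)
        study = make_breast(spec)
        noisy = add_noise(
            study, NoiseModel("rician", snr_sigma(spec.s0, snr), seed + 1000 * k + 1))
        trace = compute_trace(noisy)
        out.append(SimulatedDataset(f"Br{len(b_values)}b-{k + 1:02d}", trace,
                                    make_tumor_roi(spec)))
    return out


def measure(datasets: list[SimulatedDataset], metrics: list[str],
            implementations: dict[str, FitConfig] | None = None) -> pd.DataFrame:
    """Fit every (implementation, dataset, metric) and pool the ROI means."""
    implementations = implementations or DEFAULT_IMPLEMENTATIONS
    rows = []
    for ds in datasets:
        for impl, cfg in implementations.items():
            for metric in metrics:
                pmap = fit_volume(ds.study, cfg, metric)
                stats = apply_rois(pmap, ds.rois)
                rows.append(stats_to_rows(stats, impl, ds.dataset_id, metric))
    return pd.concat(rows, ignore_index=True)


def run_concordance(table: pd.DataFrame, metric: str,
                    threshold: float = 0.1,
                    reference_mode: str = "group_average") -> ConcordanceReport:
    return analyze(table, metric, threshold, reference_mode)
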