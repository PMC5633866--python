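#!/usr/bin/env python
"""Centralized harmonization and ROI analysis of the submitted maps.

Emulates what a coordinating site must do before pooling: three maps are
deliberately corrupted the way real submissions were (one loses its
intensity-rescale factor, one arrives with reversed slice order, one
carries not-a-number pixels), then every map is harmonized against the
AI-LL1 reference map for its dataset/metric and reduced to ROI means
(13 one-cm vial circles for phantoms, the multislice tumor mask for breast
studies).  Output: results/measurements.csv.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from adcconcord.mapio import harmonize, read_map
from adcconcord.pipeline import DEFAULT_IMPLEMENTATIONS
from adcconcord.roi import apply_rois, make_tumor_roi, make_vial_rois, stats_to_rows
from adcconcord.synth import corrupt, default_breast_spec, default_phantom_spec

MAPS = ROOT / "scratch" / "maps"
METRICS = {"phantom": ["ADC4", "ADChi-low"],
           "breast": ["ADC4", "ADCslow", "PerfFrac"]}
REFERENCE_IMPL = "AI-LL1"

# (dataset index among breast sets, implementation) -> corruption applied
CORRUPTIONS = {
    ("Br4b-01", "AI-NLS1"): "drop_rescale",
    ("Br4b-02", "AI-LL2"): "reverse_slices",
    ("Br4b-03", "AI-NLS2"): "inject_nan",
}


def main() -> None:
    manifest = json.loads((ROOT / "results" / "study_manifest.json").read_text())
    rois_by_id = {}
    for entry in manifest["datasets"]:
        if entry["kind"] == "phantom":
            rois_by_id[entry["id"]] = make_vial_rois(default_phantom_spec())
        else:
            k = int(entry["id"].split("-")[-1]) - 1
            spec = default_breast_spec(seed=entry["cohort_seed"] + 1000 * k)
            rois_by_id[entry["id"]] = make_tumor_roi(spec)

    rows = []
    n_corrupted = 0
    for entry in manifest["datasets"]:
        ds = entry["id"]
        for metric in METRICS[entry["kind"]]:
            ref = read_map(MAPS / ds / f"{REFERENCE_IMPL}_{metric}.nii.gz")
            for impl in DEFAULT_IMPLEMENTATIONS:
                pmap = read_map(MAPS / ds / f"{impl}_{metric}.nii.gz")
                mode = CORRUPTIONS.get((ds, impl))
                if mode is not None and metric == "ADC4":
                    if mode == "drop_rescale":
                        # the site stored in 1e-3 mm^2/s display units
                        pmap.values = pmap.values / 1000.0
                        pmap.rescale_factor = 1000.0
                    kw = {"count": 40} if mode == "inject_nan" else {}
                    pmap = corrupt(pmap, mode, **kw)
                    n_corrupted += 1
                    print(f"corrupted {ds}/{impl}/{metric} with {mode}")
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    fixed = harmonize(pmap, reference=ref)
                for w in caught:
                    print(f"  harmonize[{ds}/{impl}/{metric}]: {w.message}")
                stats = apply_rois(fixed, rois_by_id[ds])
                rows.append(stats_to_rows(stats, impl, ds, metric))

    table = pd.concat(rows, ignore_index=True)
    out = ROOT / "results" / "measurements.csv"
    table.to_csv(out, index=False)
    print(f"{n_corrupted} maps corrupted and recovered; "
          f"{len(table)} ROI measurements -> {out}")


if __name__ == "__main__":
    main()
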