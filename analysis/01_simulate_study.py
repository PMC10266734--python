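#!/usr/bin/env python
"""Generate the synthetic pharmacological study analysed by the later steps.

Writes a full planted study under results/study/: a 100-region spherical
parcellation, a 19-map receptor panel, a 15-drug contrast panel whose
cross-covariance with the receptors carries one planted latent (snr=4),
subject-level baseline/drug BOLD scans realizing the planted degree change
for the first drug, and 11 disorder maps coupled (0.5) to the drug panel.
"""

import json
from pathlib import Path

import numpy as np

import pharmaconet as pn

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    geom = pn.make_geometry(100, seed=SEED)
    X = pn.make_receptor_panel(geom, 19, seed=SEED)
    Y, truth = pn.plant_drug_effects(X, geom, n_drugs=15, k_latent=1, snr=4.0,
                                     seed=SEED)
    D = pn.make_disorder_maps(Y, geom, n_disorders=11, coupling=0.5, seed=SEED)
    pn.write_geometry(geom, OUT / "geometry.tsv")
    pn.write_regional_table(X, OUT / "receptors.tsv")
    pn.write_regional_table(Y, OUT / "drugs.tsv")
    pn.write_regional_table(D, OUT / "disorders.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "true_weights": truth.true_weights.tolist(),
        "true_delta": truth.true_delta.tolist(),
    }, indent=2))

    scans = pn.make_subject_scans(geom, truth.true_delta, n_subjects=15,
                                  n_timepoints=250, effect_gain=1.0,
                                  seed=SEED + 1000)
    scans_dir = OUT / "scans"
    scans_dir.mkdir(exist_ok=True)
    for pair in scans:
        for cond, ts in (("baseline", pair.baseline_ts), ("drug", pair.drug_ts)):
            tbl = pn.RegionalMatrix(geom.region_ids,
                                    [f"t{t}" for t in range(ts.shape[1])], ts)
            pn.write_regional_table(tbl, scans_dir / f"drug_00_{pair.subject_id}_{cond}.tsv")
    print(f"study written to {OUT}")
    print(f"  receptors: {X.values.shape}, drugs: {Y.values.shape}, "
          f"disorders: {D.values.shape}, scans: {len(scans)} subjects x 2 conditions")


if __name__ == "__main__":
    main()
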