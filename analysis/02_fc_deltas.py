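#!/usr/bin/env python
"""Compute subject-wise and group FC weighted-degree delta maps.

Reads the study scans written by 01_simulate_study.py, builds each
subject's drug-minus-baseline change in positive FC weighted degree, and
reports how well the group-mean delta map recovers the planted one.
Writes results/deltas/drug_00_{subjects,mean}.tsv.
"""

import json
from pathlib import Path

import numpy as np

import pharmaconet as pn
from pharmaconet.datatypes import SubjectScanPair

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    geom = pn.read_geometry(ROOT / "study" / "geometry.tsv")
    truth = json.loads((ROOT / "study" / "truth.json").read_text())
    scans_dir = ROOT / "study" / "scans"
    deltas = []
    subjects = sorted({f.stem.rsplit("_", 1)[0]
                       for f in scans_dir.glob("drug_00_*_baseline.tsv")})
    for stem in subjects:
        base = pn.read_regional_table(scans_dir / f"{stem}_baseline.tsv", geom)
        drug = pn.read_regional_table(scans_dir / f"{stem}_drug.tsv", geom)
        pair = SubjectScanPair(stem, base.values, drug.values)
        deltas.append(pn.subject_delta(pair))
    dset = pn.aggregate_dataset(deltas, "drug_00", geom.region_ids)

    out = ROOT / "deltas"
    out.mkdir(parents=True, exist_ok=True)
    pn.write_regional_table(
        pn.RegionalMatrix(geom.region_ids,
                          [s.split("drug_00_")[1] for s in subjects],
                          dset.subject_deltas), out / "drug_00_subjects.tsv")
    pn.write_regional_table(
        pn.RegionalMatrix(geom.region_ids, ["drug_00"], dset.mean_delta[:, None]),
        out / "drug_00_mean.tsv")

    r = np.corrcoef(dset.mean_delta, np.array(truth["true_delta"]))[0, 1]
    print(f"{dset.n_subjects} subjects; group delta vs planted delta: r = {r:.3f}")


if __name__ == "__main__":
    main()
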