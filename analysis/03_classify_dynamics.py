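#!/usr/bin/env python
"""Classify binding dynamics and SE patterns, then track transitions.

Labels every peak primary/persistent/secondary across the contrast,
classifies each SE as SE1-SE3 (after) or SE4-SE6 (before), and follows
each before-SE to its fate after stimulation.
"""

import json
from pathlib import Path

import pandas as pd

from sigse import binding_dynamics as dyn
from sigse.pipeline import _fate_census, _patterns_table, _transitions_table
from sigse.intervals import read_bed, remove_blacklisted
from sigse.se_detection import StitchedEnhancer

DIR = Path("results/analysis")


def load_ses(path):
    return [StitchedEnhancer(p.interval, (p,)) for p in read_bed(path, "bed6")]


def main() -> None:
    inputs = DIR / "inputs"
    blacklist = [p.interval for p in read_bed(inputs / "blacklist.bed", "bed3")]
    peaks_b = remove_blacklisted(
        read_bed(inputs / "peaks_before.narrowPeak", "narrowPeak"), blacklist
    )
    peaks_a = remove_blacklisted(
        read_bed(inputs / "peaks_after.narrowPeak", "narrowPeak"), blacklist
    )
    labels_b, labels_a = dyn.label_sites(peaks_b, peaks_a)
    n_pers = sum(l.label is dyn.SiteLabel.PERSISTENT for l in labels_b)
    print(
        f"sites: {len(labels_b)} before / {len(labels_a)} after, "
        f"{n_pers} persistent"
    )
    patterns_b = [
        dyn.classify_se(se, labels_b, "before") for se in load_ses(DIR / "before.SE.bed")
    ]
    patterns_a = [
        dyn.classify_se(se, labels_a, "after") for se in load_ses(DIR / "after.SE.bed")
    ]
    trans = dyn.transitions(patterns_b, patterns_a)
    _patterns_table(patterns_b + patterns_a).to_csv(
        DIR / "patterns.tsv", sep="\t", index=False
    )
    _transitions_table(trans).to_csv(DIR / "transitions.tsv", sep="\t", index=False)
    census = {
        "before": dyn.pattern_census(patterns_b),
        "after": dyn.pattern_census(patterns_a),
    }
    (DIR / "census.json").write_text(json.dumps(census, indent=1) + "\n")
    print("after-stimulation census:",
          {k: v for k, v in census["after"].items() if v})
    print("before-stimulation census:",
          {k: v for k, v in census["before"].items() if v})
    print("transition fates:", _fate_census(trans))


if __name__ == "__main__":
    main()
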