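#!/usr/bin/env python
"""Score clinical phenotypes from the cohort's longitudinal tables.

Computes per-subject side-effect profiles (9 cluster scores, global S,
general component GSIDE, specific components SEX/AUTO/NEURO/CARDIO, severity
stratum) at the day-10 assessment with LOCF fill-in, plus outcome records
(response, onset of improvement, baseline severity, 3-week weight change).
"""
import argparse
from pathlib import Path

from sidefx import io
from sidefx.phenotypes import build_outcomes, score_profiles


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--day", type=float, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    medis = io.read_medis(args.indir)
    profiles = score_profiles(medis, day=args.day)
    outcomes = build_outcomes(io.read_subjects(args.indir),
                              io.read_scale_scores(args.indir),
                              io.read_weights(args.indir))
    args.out.mkdir(parents=True, exist_ok=True)
    profiles.to_csv(args.out / "profiles.tsv", sep="\t")
    outcomes.to_csv(args.out / "outcomes.tsv", sep="\t")

    strata = profiles["stratum"].value_counts(normalize=True)
    print(f"profiles for {len(profiles)} subjects at day {args.day:g}")
    print("global severity strata:",
          ", ".join(f"{k} {100 * v:.1f}%" for k, v in strata.items()))
    resp = outcomes["responder"].dropna().astype(bool)
    print(f"responders: {100 * resp.mean():.1f}% of {len(resp)}")
    w = outcomes["weight_delta_kg"].dropna()
    print(f"weight gain >= 2 kg: {100 * (w >= 2).mean():.1f}% of {len(w)} "
          f"(mean {w.mean():.2f} kg)")


if __name__ == "__main__":
    main()
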