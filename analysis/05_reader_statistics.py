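"""Score a (synthetic) reader study and compare sessions statistically.

Simulates three readers' 3-label responses over the study's session design
(session 2: 100 real images; session 3: 436 half-real/half-fake; session 5:
440 after the educational intervention), scores each session into the
accuracy breakdown, and computes one-sided p-values between sessions using
reading-order subgroup SDs.

Usage: python analysis/05_reader_statistics.py [--seed 0] [--subgroups 4]
       [--responses <csv>]   # to score a real table instead of simulating
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from advcad import reader as rd  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--subgroups", type=int, default=4)
    ap.add_argument("--responses", default=None)
    ap.add_argument("--out", default="results/study")
    args = ap.parse_args()

    if args.responses:
        responses = rd.load_responses(args.responses)
        print(f"scoring {args.responses}")
    else:
        responses = rd.simulate_reader_responses(seed=args.seed)
        print("scoring simulated responses (synthetic readers)")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = rd.reader_table(responses)
    table.to_csv(out / "reader_table.csv", index=False)
    comparisons = rd.compare_all_sessions(responses, n_subgroups=args.subgroups)
    comparisons.to_csv(out / "reader_comparisons.csv", index=False)

    cols = ["reader_id", "session", "n", "accuracy_mixed", "accuracy_real",
            "accuracy_fake", "unsure_fraction"]
    print(table[cols].round(3).to_string(index=False))
    print()
    print(comparisons.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
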