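"""Train the CAD classifier on the phantom cohort.

Loads the cohort written by 01_generate_cohort.py (or generates it), trains
the desk-profile classifier with the composite focal + input-gradient-
penalty loss in two stages, and writes the checkpoint and the per-epoch
training log under results/study/.

Usage: python analysis/02_train_classifier.py [--seed 0]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from advcad import classifier as cl  # noqa: E402
from advcad import phantom as ph  # noqa: E402
from advcad import pipeline  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", default="results/study/cohort")
    ap.add_argument("--out", default="results/study")
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    if (cohort_dir / "manifest.csv").exists():
        split = ph.load_cohort(cohort_dir)
        print(f"loaded cohort from {cohort_dir}")
    else:
        split = ph.generate_cohort(ph.PhantomConfig(seed=args.seed))
        print("generated cohort in memory (run 01_generate_cohort.py to persist)")

    trained = cl.train_classifier(split, opt=cl.desk_optimizer(), seed=args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pipeline.save_model(trained.model, out / "classifier.npz", {
        "kind": "cad_classifier", "best_epoch": trained.best_epoch,
        "best_val_auc": trained.best_val_auc})
    trained.log.to_csv(out / "classifier_log.csv", index=False)
    print(f"best validation AUC {trained.best_val_auc:.3f} "
          f"at epoch {trained.best_epoch}")
    print(f"checkpoint: {out / 'classifier.npz'}")


if __name__ == "__main__":
    main()
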