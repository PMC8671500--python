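"""Train the two adversarial generators (lesion removal and insertion).

Each GAN follows the three-phase schedule: identity pretraining of the
U-Net generator, discriminator final-layer warm-up, then alternating
adversarial training with one generator update per five discriminator
batches. Writes generator checkpoints and the per-phase training logs.

Usage: python analysis/03_train_gans.py [--seed 0] [--direction both]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from advcad import gan  # noqa: E402
from advcad import phantom as ph  # noqa: E402
from advcad import pipeline  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--direction", default="both",
                    choices=["both", "remove_lesion", "insert_lesion"])
    ap.add_argument("--cohort", default="results/study/cohort")
    ap.add_argument("--cad", default="results/study/classifier.npz")
    ap.add_argument("--out", default="results/study")
    args = ap.parse_args()

    split = ph.load_cohort(Path(args.cohort))
    model = pipeline.load_classifier(args.cad)
    import pandas as pd
    from advcad.classifier import TrainedClassifier, desk_backbone
    trained = TrainedClassifier(model=model, spec=desk_backbone(),
                                log=pd.DataFrame(), best_epoch=-1,
                                best_val_auc=float("nan"))

    directions = ([args.direction] if args.direction != "both"
                  else ["remove_lesion", "insert_lesion"])
    out = Path(args.out)
    for direction in directions:
        g = gan.train_gan(direction, split, trained, seed=args.seed)
        pipeline.save_model(g.model, out / f"generator_{direction}.npz",
                            {"kind": "unet_generator", "direction": direction})
        g.log.to_csv(out / f"gan_log_{direction}.csv", index=False)
        final = g.log.iloc[-1]
        print(f"{direction}: finished in phase {final['phase']} "
              f"(epoch {int(final['epoch'])}), final margin "
              f"{final['margin']:.4f}" if final["phase"] != "A" else
              f"{direction}: identity loss {final['loss_gen1']:.4f}")


if __name__ == "__main__":
    main()
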