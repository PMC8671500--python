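"""Attack the classifier with the GAN counterfeits and tabulate fool rates.

Every test image gets a label-flipped counterfeit from the appropriate
generator; the classifier scores both. Reports AUC on the real test set
(true labels), AUC on the adversarial set (flipped labels), per-class
correct-classification percentages, per-class and pooled fool rates, and
writes education panels (real | fake | difference) for a few positives.

Usage: python analysis/04_attack_evaluation.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from advcad import attack as at  # noqa: E402
from advcad import classifier as cl  # noqa: E402
from advcad import gan  # noqa: E402
from advcad import phantom as ph  # noqa: E402
from advcad import pipeline  # noqa: E402


def main():
    base = Path("results/study")
    split = ph.load_cohort(base / "cohort")
    model = pipeline.load_classifier(base / "classifier.npz")
    generators = {
        d: gan.AdversarialGenerator(
            model=pipeline.load_generator(base / f"generator_{d}.npz"),
            direction=d, schedule=gan.desk_gan_schedule(),
            log=pd.DataFrame(), update_log=[])
        for d in ("remove_lesion", "insert_lesion")
    }

    records, panels = [], 0
    for img in split.test:
        direction = ("remove_lesion" if img.label == "positive"
                     else "insert_lesion")
        pair = gan.generate_adversarial(generators[direction], img)
        records.append(at.AttackRecord(
            img.image_id, img.label,
            cl.predict_prob(model, pair.real),
            cl.predict_prob(model, pair.fake)))
        if direction == "remove_lesion" and panels < 3:
            at.save_education_panel(pair.real.pixels, pair.fake.pixels,
                                    base / f"education_panel_{panels}.png")
            panels += 1

    report = at.fool_rate_report(records)
    (base / "fool_rate_report.json").write_text(
        json.dumps(report.to_dict(), indent=1))
    (base / "fool_rate_report.txt").write_text(report.to_text() + "\n")
    print(report.to_text())


if __name__ == "__main__":
    main()
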