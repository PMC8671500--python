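"""Reader-study scoring: session accuracies, subgroup SDs, session p-values.

Five radiologist readers assessed, over five sessions, whether displayed
images were real mammograms or GAN-generated fakes, with a 3-label response
(real / fake / unsure). This module scores response tables into the study's
accuracy breakdown (mixed, real-only, fake-only, and the four truth-class
strata, plus an unsure fraction), estimates the accuracy's standard
deviation by splitting each session's readings, in reading order, into
non-overlapping equal-size subgroups, and compares sessions with one-sided
normal-approximation p-values using the averaged subgroup SD as the scale.

An "unsure" response is never correct (it is reported in its own column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["reader_id", "session", "image_id", "order_index",
                    "truth_realness", "truth_class", "response"]

# truth_class values: positive / negative (real images),
#                     positive-looking / negative-looking (fakes)
STRATA = ["positive", "negative", "positive-looking", "negative-looking"]


@dataclass
class ReaderResponse:
    reader_id: str
    session: int
    image_id: str
    order_index: int
    truth_realness: str              # "real" | "fake"
    truth_class: str
    response: str                    # "real" | "fake" | "unsure"


@dataclass
class SessionSummary:
    reader_id: str
    session: int
    n: int
    accuracy_overall: float
    accuracy_real: float | None
    accuracy_fake: float | None
    accuracy_by_class: dict[str, float | None]
    unsure_fraction: float


@dataclass
class SessionComparison:
    reader_id: str
    session_a: int
    session_b: int
    accuracy_a: float
    accuracy_b: float
    sd_avg: float
    n_subgroups: int
    one_sided_p: float


def _as_frame(responses) -> pd.DataFrame:
    if isinstance(responses, pd.DataFrame):
        df = responses.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in responses])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing response columns: {missing}")
    return df


def _correct(df: pd.DataFrame) -> pd.Series:
    """A response is correct iff it names the truth_realness; 'unsure' never is."""
    return df["response"] == df["truth_realness"]


def session_accuracy(responses) -> SessionSummary:
    """Score one (reader, session) block of responses."""
    df = _as_frame(responses)
    if df.empty:
        raise ValueError("no responses to score")
    if df["reader_id"].nunique() != 1 or df["session"].nunique() != 1:
        raise ValueError("responses must come from a single reader and session")
    if df.duplicated(subset=["order_index"]).any():
        raise ValueError("order_index must be unique within a session")
    correct = _correct(df)

    def acc(mask) -> float | None:
        return None if mask.sum() == 0 else float(correct[mask].mean())

    by_class = {s: acc(df["truth_class"] == s) for s in STRATA}
    return SessionSummary(
        reader_id=str(df["reader_id"].iloc[0]),
        session=int(df["session"].iloc[0]),
        n=len(df),
        accuracy_overall=float(correct.mean()),
        accuracy_real=acc(df["truth_realness"] == "real"),
        accuracy_fake=acc(df["truth_realness"] == "fake"),
        accuracy_by_class=by_class,
        unsure_fraction=float((df["response"] == "unsure").mean()),
    )


def subgroup_sd(responses, n_subgroups: int = 4) -> float:
    """Sample SD of per-subgroup accuracies.

    The responses are ordered by ``order_index`` and cut into
    ``n_subgroups`` contiguous blocks of equal size (any trailing remainder
    is dropped and logged); the SD is the ddof=1 standard deviation of the
    block accuracies.
    """
    if n_subgroups < 2:
        raise ValueError("need at least 2 subgroups")
    df = _as_frame(responses).sort_values("order_index")
    block = len(df) // n_subgroups
    if block == 0:
        raise ValueError("session smaller than the number of subgroups")
    dropped = len(df) - block * n_subgroups
    if dropped:
        logger.info("subgroup_sd: dropping %d trailing responses", dropped)
    correct = _correct(df).to_numpy()[: block * n_subgroups]
    accs = correct.reshape(n_subgroups, block).mean(axis=1)
    return float(np.std(accs, ddof=1))


def compare_sessions(acc_a: float, acc_b: float, sd_avg: float) -> float:
    """One-sided p-value for the hypothesis that session b improved on a.

    Each session accuracy is treated as normal with scale ``sd_avg``;
    z = (acc_b - acc_a) / (sd_avg * sqrt(2)) and p = 1 - Phi(z), so a larger
    improvement yields a smaller p. With sd_avg = 0 the comparison is
    degenerate: p is 0 or 1 by the sign of the difference (0.5 on a tie).
    """
    if sd_avg < 0:
        raise ValueError("sd_avg must be non-negative")
    if sd_avg == 0:
        logger.warning("compare_sessions: sd_avg is 0; degenerate p-value")
        return 0.5 if acc_b == acc_a else (0.0 if acc_b > acc_a else 1.0)
    z = (acc_b - acc_a) / (sd_avg * np.sqrt(2.0))
    return float(1.0 - norm.cdf(z))


def compare_all_sessions(responses, sessions=(2, 3, 5),
                         n_subgroups: int = 4) -> pd.DataFrame:
    """Pairwise one-sided comparisons per reader across the given sessions,
    using the average of the sessions' subgroup SDs as the common scale."""
    df = _as_frame(responses)
    rows = []
    for reader, group in df.groupby("reader_id"):
        have = [s for s in sessions if (group["session"] == s).any()]
        if len(have) < 2:
            continue
        sds = {s: subgroup_sd(group[group["session"] == s], n_subgroups)
               for s in have}
        accs = {s: session_accuracy(group[group["session"] == s]).accuracy_overall
                for s in have}
        sd_avg = float(np.mean(list(sds.values())))
        for i, sa in enumerate(have):
            for sb in have[i + 1:]:
                rows.append(SessionComparison(
                    reader_id=str(reader), session_a=sa, session_b=sb,
                    accuracy_a=accs[sa], accuracy_b=accs[sb],
                    sd_avg=sd_avg, n_subgroups=n_subgroups,
                    one_sided_p=compare_sessions(accs[sa], accs[sb], sd_avg),
                ).__dict__)
    return pd.DataFrame(rows)


def reader_table(responses) -> pd.DataFrame:
    """Full accuracy grid (reader x session x strata), one row per
    (reader, session)."""
    df = _as_frame(responses)
    rows = []
    for (reader, session), group in df.groupby(["reader_id", "session"]):
        s = session_accuracy(group)
        row = {
            "reader_id": s.reader_id, "session": s.session, "n": s.n,
            "accuracy_mixed": s.accuracy_overall,
            "accuracy_real": s.accuracy_real,
            "accuracy_fake": s.accuracy_fake,
            "unsure_fraction": s.unsure_fraction,
        }
        for stratum in STRATA:
            row[f"accuracy_{stratum.replace('-', '_')}"] = s.accuracy_by_class[stratum]
        n_real = int((group["truth_realness"] == "real").sum())
        row["n_real"], row["n_fake"] = n_real, s.n - n_real
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["reader_id", "session"]).reset_index(drop=True)


def load_responses(path) -> pd.DataFrame:
    return _as_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# synthetic response tables (no human readings are collected here)
# ---------------------------------------------------------------------------

# per-session image mix: (real positive, real negative,
#                         positive-looking fake, negative-looking fake)
DEFAULT_SESSION_DESIGN: dict[int, tuple[int, int, int, int]] = {
    2: (49, 51, 0, 0),
    3: (36, 179, 183, 38),
    5: (39, 184, 180, 37),
}


def simulate_reader_responses(
        reader_profiles: dict[str, dict[int, tuple[float, float, float]]] | None = None,
        design: dict[int, tuple[int, int, int, int]] | None = None,
        seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic response table for the scoring pipeline.

    ``reader_profiles`` maps reader_id -> {session: (p_correct_real,
    p_correct_fake, p_unsure)}; a response is "unsure" with probability
    p_unsure, otherwise correct with the class-appropriate probability and
    wrong with the remainder. The default profiles emulate readers whose
    fake-detection improves in later sessions. Purely synthetic stand-in
    data for exercising the statistics; it models no real reader behavior.
    """
    design = design or DEFAULT_SESSION_DESIGN
    if reader_profiles is None:
        reader_profiles = {
            "R1": {2: (0.85, 0.5, 0.05), 3: (0.9, 0.35, 0.02), 5: (0.85, 0.5, 0.03)},
            "R2": {2: (0.6, 0.5, 0.0), 3: (0.65, 0.5, 0.0), 5: (0.5, 0.65, 0.0)},
            "R3": {2: (0.9, 0.5, 0.03), 3: (0.95, 0.35, 0.03), 5: (0.95, 0.5, 0.03)},
        }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EAD]))
    rows = []
    for reader, sessions in reader_profiles.items():
        for session, (p_real, p_fake, p_unsure) in sessions.items():
            counts = design[session]
            truths = (
                [("real", "positive")] * counts[0]
                + [("real", "negative")] * counts[1]
                + [("fake", "positive-looking")] * counts[2]
                + [("fake", "negative-looking")] * counts[3]
            )
            order = rng.permutation(len(truths))
            for pos, idx in enumerate(order):
                realness, cls = truths[idx]
                u = rng.random()
                p_corr = p_real if realness == "real" else p_fake
                if u < p_unsure:
                    resp = "unsure"
                elif rng.random() < p_corr:
                    resp = realness
                else:
                    resp = "fake" if realness == "real" else "real"
                rows.append({
                    "reader_id": reader, "session": session,
                    "image_id": f"s{session}_img{idx:04d}",
                    "order_index": pos, "truth_realness": realness,
                    "truth_class": cls, "response": resp,
                })
    return pd.DataFrame(rows)
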