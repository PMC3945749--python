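"""Matching experiments: full-library ranking and the replicated trial design.

Two designs are implemented:

1. *Full-library analysis* — every mimic call is queried against all other
   files in the library and the rank of its putative model is recorded,
   for each feature representation x similarity index. The resulting
   rank-1/2/3 count table drives the choice of one feature and two
   indices (most first-ranked correct matches; rank-assignment variance
   as consistency check).

2. *Trial experiment* — the design used for both the automated and the
   human-assessment arms: each mimic is tested in ``reps`` (default 5)
   sets of 11 spectrogram slots: the query plus 10 candidates (its
   putative model, 3 other mimics, 3 conspecific and 3 other-species
   calls drawn at random). Accuracy is scored per trial (rank-1 and
   rank-1+2 proportions) and per call (correct in all 5 trials, or in at
   least 4 of 5 — the 80 % threshold criterion).

Two arms are compared with the Yates-corrected two-sample proportion test.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_KINDS, extract_features
from .similarity import METRIC_ORDER, FeatureVector, pool_frames, rank_library
from .stats import ProportionTestResult, yates_prop_test
from .synth import CallLibrary

#: candidate composition of one trial set (besides the putative model)
N_DISTRACTOR_MIMIC = 3
N_DISTRACTOR_CONSPECIFIC = 3
N_DISTRACTOR_OTHER = 3
CANDIDATES_PER_SET = 1 + N_DISTRACTOR_MIMIC + N_DISTRACTOR_CONSPECIFIC + N_DISTRACTOR_OTHER


@dataclass(frozen=True)
class TrialSet:
    set_id: str
    query_id: str
    candidate_ids: tuple[str, ...]
    model_id: str

    def __post_init__(self) -> None:
        if len(self.candidate_ids) != CANDIDATES_PER_SET:
            raise ValueError(f"trial set must hold {CANDIDATES_PER_SET} candidates")
        if self.candidate_ids.count(self.model_id) != 1:
            raise ValueError("putative model must appear exactly once among candidates")
        if self.query_id in self.candidate_ids:
            raise ValueError("query must not appear among its own candidates")

    @property
    def n_spectrograms(self) -> int:
        """Slots shown in one set: the query plus its candidates."""
        return 1 + len(self.candidate_ids)


class RankCountTable:
    """Correct-match counts at ranks 1-3 per (feature kind, metric)."""

    def __init__(self) -> None:
        self.counts: dict[tuple[str, str], dict[str, int]] = {}

    def add(self, feature: str, metric: str, ranks: list[int]) -> None:
        c = {"rank1": 0, "rank2": 0, "rank3": 0, "incorrect": 0}
        for r in ranks:
            if r <= 3:
                c[f"rank{r}"] += 1
            else:
                c["incorrect"] += 1
        self.counts[(feature, metric)] = c

    def get(self, feature: str, metric: str) -> dict[str, int]:
        return self.counts[(feature, metric)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "metric": m, **c} for (f, m), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ExperimentReport:
    """Per-call model ranks across trials, with the aggregate criteria."""

    ranks: dict[str, list[int]] = field(default_factory=dict)
    feature: str = ""
    metric: str = ""

    def add_trial(self, call_id: str, rank: int) -> None:
        self.ranks.setdefault(call_id, []).append(rank)

    @property
    def n_calls(self) -> int:
        return len(self.ranks)

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.ranks.values())

    # -- trial-level criteria ------------------------------------------
    def trial_correct_count(self, max_rank: int = 1) -> int:
        return sum(r <= max_rank for v in self.ranks.values() for r in v)

    def trial_accuracy(self, max_rank: int = 1) -> float:
        return self.trial_correct_count(max_rank) / self.n_trials

    # -- call-level criteria -------------------------------------------
    def calls_all_correct(self, max_rank: int = 1) -> list[str]:
        return [c for c, v in self.ranks.items() if all(r <= max_rank for r in v)]

    def calls_threshold(self, max_rank: int = 1, min_correct: int = 4) -> list[str]:
        """Calls correct in at least ``min_correct`` trials (80 % criterion)."""
        return [
            c for c, v in self.ranks.items() if sum(r <= max_rank for r in v) >= min_correct
        ]

    def misclassified_calls(self, max_rank: int = 2) -> list[str]:
        """Calls never matched within ``max_rank`` in any trial."""
        return [c for c, v in self.ranks.items() if all(r > max_rank for r in v)]

    def summary(self) -> dict[str, float]:
        return {
            "n_calls": self.n_calls,
            "n_trials": self.n_trials,
            "trial_rank1_prop": self.trial_accuracy(1),
            "trial_rank12_prop": self.trial_accuracy(2),
            "calls_all5_rank1": len(self.calls_all_correct(1)),
            "calls_4of5_rank1": len(self.calls_threshold(1)),
        }

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["call_id", "trial", "rank"])
            for call_id, ranks in self.ranks.items():
                for t, r in enumerate(ranks, start=1):
                    w.writerow([call_id, t, r])

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ExperimentReport":
        """Ingest trial outcomes (e.g. a human-assessment arm) from CSV."""
        report = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                report.add_trial(row["call_id"], int(row["rank"]))
        return report


# ---------------------------------------------------------------------------
# trial-set construction


def build_trial_sets(library: CallLibrary, reps: int = 5, seed: int = 0) -> list[TrialSet]:
    """Build ``n_mimics * reps`` candidate sets, each of 11 spectrogram slots.

    Distractors are drawn without replacement within a set and
    independently across sets; candidate order is shuffled by the seed.
    """
    rng = np.random.default_rng(seed)
    mimic_ids = library.ids_with_role("mimic")
    pools = {
        "mimic": mimic_ids,
        "conspecific": library.ids_with_role("conspecific"),
        "other": library.ids_with_role("other"),
    }
    needs = {
        "mimic": N_DISTRACTOR_MIMIC + 1,  # +1: the query itself is excluded
        "conspecific": N_DISTRACTOR_CONSPECIFIC,
        "other": N_DISTRACTOR_OTHER,
    }
    for role, need in needs.items():
        if len(pools[role]) < need:
            raise ValueError(
                f"library has {len(pools[role])} {role} calls, need at least {need}"
            )

    sets: list[TrialSet] = []
    for mid in mimic_ids:
        model_id = library.by_id[mid].model_id
        others = [m for m in mimic_ids if m != mid]
        for rep in range(reps):
            cand = [model_id]
            cand += list(rng.choice(others, N_DISTRACTOR_MIMIC, replace=False))
            cand += list(rng.choice(pools["conspecific"], N_DISTRACTOR_CONSPECIFIC, replace=False))
            cand += list(rng.choice(pools["other"], N_DISTRACTOR_OTHER, replace=False))
            rng.shuffle(cand)
            sets.append(
                TrialSet(
                    set_id=f"set_{len(sets):03d}",
                    query_id=mid,
                    candidate_ids=tuple(cand),
                    model_id=model_id,
                )
            )
    return sets


# ---------------------------------------------------------------------------
# running the analyses


def pooled_vectors(
    library: CallLibrary, feature: str, pooling: str = "mean", ids: list[str] | None = None
) -> dict[str, FeatureVector]:
    """Pooled feature vector for each requested clip (all clips by default)."""
    if ids is None:
        ids = [c.id for c in library.clips]
    return {
        cid: pool_frames(extract_features(library.by_id[cid], feature), pooling)
        for cid in ids
    }


def run_library_analysis(
    library: CallLibrary,
    features: tuple[str, ...] = FEATURE_KINDS,
    metrics: tuple[str, ...] = METRIC_ORDER,
    pooling: str = "mean",
) -> tuple[RankCountTable, pd.DataFrame]:
    """Rank each mimic's model among all other files, per feature x metric."""
    if len(library) < 2:
        raise ValueError("library analysis needs at least two files")
    mimics = [c for c in library.mimics if c.model_id is not None]
    table = RankCountTable()
    detail_rows = []
    for feature in features:
        vectors = pooled_vectors(library, feature, pooling)
        for metric in metrics:
            ranks = []
            for mimic in mimics:
                candidates = {cid: v for cid, v in vectors.items() if cid != mimic.id}
                ranked = rank_library(vectors[mimic.id], candidates, metric, mimic.id)
                rank = ranked.rank_of(mimic.model_id)
                ranks.append(rank)
                detail_rows.append(
                    {"feature": feature, "metric": metric, "mimic": mimic.id, "rank": rank}
                )
            table.add(feature, metric, ranks)
    return table, pd.DataFrame(detail_rows)


def run_trial_experiment(
    library: CallLibrary,
    sets: list[TrialSet],
    feature: str,
    metric: str,
    pooling: str = "mean",
) -> ExperimentReport:
    """Score the model's rank among the 10 candidates of every trial set."""
    ids = sorted({s.query_id for s in sets} | {c for s in sets for c in s.candidate_ids})
    vectors = pooled_vectors(library, feature, pooling, ids)
    report = ExperimentReport(feature=feature, metric=metric)
    for s in sets:
        candidates = {cid: vectors[cid] for cid in s.candidate_ids}
        ranked = rank_library(vectors[s.query_id], candidates, metric, s.query_id)
        report.add_trial(s.query_id, ranked.rank_of(s.model_id))
    return report


# ---------------------------------------------------------------------------
# rank variance and selection


def rank_variance(
    counts: tuple[int, int, int],
    include_incorrect_as_4: bool = False,
    n_incorrect: int = 0,
) -> float:
    """Sample variance of the rank list expanded from rank-1/2/3 counts.

    With the flag set, incorrect matches are appended as rank 4 (the
    lowest rank) before the variance is taken.
    """
    if any(c < 0 for c in counts) or n_incorrect < 0:
        raise ValueError("counts must be non-negative")
    ranks = [1] * counts[0] + [2] * counts[1] + [3] * counts[2]
    if include_incorrect_as_4:
        ranks += [4] * n_incorrect
    if len(ranks) < 2:
        raise ValueError("rank variance needs at least two matches")
    return float(np.var(ranks, ddof=1))


def select_feature_and_metrics(
    table: RankCountTable, variances: dict[tuple[str, str], float] | None = None
) -> tuple[str, tuple[str, str]]:
    """Pick the best feature and the two best similarity indices.

    The feature is the one with the most first-ranked correct matches
    (summed over indices). The two indices are those with the most
    first-ranked correct matches summed over *all* features; ties are
    broken by lower mean rank variance, then by the fixed index order.
    """
    if not table.counts:
        raise ValueError("empty rank-count table")
    features = sorted({f for f, _ in table.counts})
    metrics = [m for m in METRIC_ORDER if any((f, m) in table.counts for f in features)]

    def feat_total(f: str) -> int:
        return sum(table.counts[(f, m)]["rank1"] for m in metrics if (f, m) in table.counts)

    def metric_total(m: str) -> int:
        return sum(table.counts[(f, m)]["rank1"] for f in features if (f, m) in table.counts)

    if all(feat_total(f) == 0 for f in features):
        raise ValueError("no correct first-ranked matches; nothing selectable")
    best_feature = max(features, key=lambda f: (feat_total(f), f))

    def metric_key(m: str):
        var = 0.0
        if variances is not None:
            vs = [variances[(f, m)] for f in features if (f, m) in variances]
            var = float(np.mean(vs)) if vs else 0.0
        return (-metric_total(m), var, METRIC_ORDER.index(m))

    ordered = sorted(metrics, key=metric_key)
    if len(ordered) < 2:
        return best_feature, (ordered[0], ordered[0])
    return best_feature, (ordered[0], ordered[1])


# ---------------------------------------------------------------------------
# method comparison

CRITERIA = ("trials", "all_trials", "threshold")


def _criterion_counts(report: ExperimentReport, criterion: str, max_rank: int) -> tuple[int, int]:
    if criterion == "trials":
        return report.trial_correct_count(max_rank), report.n_trials
    if criterion == "all_trials":
        return len(report.calls_all_correct(max_rank)), report.n_calls
    if criterion == "threshold":
        return len(report.calls_threshold(max_rank)), report.n_calls
    raise ValueError(f"unknown criterion {criterion!r}; options: {CRITERIA}")


def compare_methods(
    report_a: ExperimentReport,
    report_b: ExperimentReport,
    criterion: str = "all_trials",
    max_rank: int = 1,
) -> tuple[ProportionTestResult, list[str]]:
    """Yates proportion test between two arms on a chosen accuracy criterion.

    Also returns the disagreement list: calls classified correctly under
    the criterion by exactly one of the two arms.
    """
    if report_a.n_calls != report_b.n_calls:
        raise ValueError("reports cover different numbers of calls")
    xa, na = _criterion_counts(report_a, criterion, max_rank)
    xb, nb = _criterion_counts(report_b, criterion, max_rank)
    result = yates_prop_test(xa, na, xb, nb)
    if criterion == "trials":
        ok_a = set(report_a.calls_threshold(max_rank, min_correct=1))
        ok_b = set(report_b.calls_threshold(max_rank, min_correct=1))
    else:
        min_c = None if criterion == "all_trials" else 4
        if criterion == "all_trials":
            ok_a, ok_b = set(report_a.calls_all_correct(max_rank)), set(
                report_b.calls_all_correct(max_rank)
            )
        else:
            ok_a = set(report_a.calls_threshold(max_rank, min_c))
            ok_b = set(report_b.calls_threshold(max_rank, min_c))
    disagreement = sorted(ok_a.symmetric_difference(ok_b))
    return result, disagreement
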