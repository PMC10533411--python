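"""Consensus quantification of particle-classification categories.

Discrete 3D classification of cryo-EM particle stacks is unstable: the
fraction of particles assigned to a category of interest (here: receptors
lacking the NTD/LBD domain swap) varies between repeated runs and with the
number of classes k.  Stability is therefore assessed by repeating the
classification (e.g. in triplicate at each k from 3 to 30), measuring how
particle subsets co-migrate between pairs of runs with the same k, and
summarizing the category fraction as mean ± s.e. over the most consistent
runs (by default those with 6–20 classes).

Category annotation (swapped / non_swapped / junk per class) is a
user-supplied input: assigning a 3D class to a category is done by map
inspection upstream and cannot be automated here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

CATEGORIES = ("swapped", "non_swapped", "junk")
DEFAULT_K_RANGE = (6, 20)
DEFAULT_CONSISTENCY_THRESHOLD = 0.6


@dataclass
class ClassificationRun:
    """One classification run: particle → class labels plus class categories."""

    run_id: str
    k: int
    labels: dict  # particle_id -> class_id
    class_categories: dict  # class_id -> category

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"run {self.run_id!r}: k must be >= 3 (got {self.k})")
        for cat in self.class_categories.values():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown class category {cat!r}")
        used = set(self.labels.values())
        missing = used - set(self.class_categories)
        if missing:
            raise ValueError(
                f"run {self.run_id!r}: classes without category annotation: "
                f"{sorted(missing)[:10]}"
            )

    @property
    def n_particles(self) -> int:
        return len(self.labels)


@dataclass
class ConsensusSummary:
    per_run_fraction: dict  # run_id -> category fraction
    comigration: dict  # (run_id, run_id) -> matched fraction
    consistent_runs: list
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n != len(self.consistent_runs):
            raise ValueError("n must equal the number of consistent runs")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def category_fraction(run: ClassificationRun, category: str) -> float:
    """Fraction of non-junk particles whose class carries ``category``."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    cats = np.array([run.class_categories[c] for c in run.labels.values()], dtype=object)
    non_junk = cats != "junk"
    denom = int(non_junk.sum())
    if denom == 0:
        raise ValueError(f"run {run.run_id!r}: no non-junk particles")
    return float((cats[non_junk] == category).sum() / denom)


def matched_fraction_from_contingency(
    contingency: np.ndarray,
) -> tuple[float, list[tuple[int, int]]]:
    """Maximum-weight one-to-one class matching on a k×k contingency matrix.

    Solved exactly as an assignment problem; returns the matched particle
    fraction and the list of matched (row, column) index pairs sorted by row.
    """
    C = np.asarray(contingency, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("contingency matrix must be square (same k)")
    total = C.sum()
    if total <= 0:
        raise ValueError("contingency matrix is empty")
    rows, cols = linear_sum_assignment(C, maximize=True)
    matched = float(C[rows, cols].sum() / total)
    return matched, sorted(zip(rows.tolist(), cols.tolist()))


def comigration_matched_fraction(
    run_a: ClassificationRun, run_b: ClassificationRun
) -> tuple[float, list[tuple[object, object]]]:
    """Fraction of particles in co-migrating class subsets between two runs.

    Both runs must classify the same particle set with the same number of
    classes.  The k×k contingency matrix of shared particles is matched
    one-to-one (maximum weight); the matched fraction is the number of
    particles falling in matched cells over all particles.
    """
    if run_a.k != run_b.k:
        raise ValueError(
            f"runs {run_a.run_id!r} and {run_b.run_id!r} have different k "
            f"({run_a.k} vs {run_b.k})"
        )
    particles_a = set(run_a.labels)
    particles_b = set(run_b.labels)
    if particles_a != particles_b:
        diff = len(particles_a ^ particles_b)
        raise ValueError(
            f"runs {run_a.run_id!r} and {run_b.run_id!r} classify different "
            f"particle sets (symmetric difference: {diff} particles)"
        )
    classes_a = sorted(run_a.class_categories)
    classes_b = sorted(run_b.class_categories)
    index_a = {c: i for i, c in enumerate(classes_a)}
    index_b = {c: i for i, c in enumerate(classes_b)}
    # pad to k x k so empty (annotated but unused) classes stay matchable
    n = max(run_a.k, run_b.k, len(classes_a), len(classes_b))
    C = np.zeros((n, n))
    for p, ca in run_a.labels.items():
        C[index_a[ca], index_b[run_b.labels[p]]] += 1
    matched, pairs = matched_fraction_from_contingency(C)
    matching = [
        (classes_a[i], classes_b[j])
        for i, j in pairs
        if i < len(classes_a) and j < len(classes_b) and C[i, j] > 0
    ]
    return matched, matching


def consensus_stats(fractions: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (sample SD / √n, n−1 denominator)."""
    fractions = np.asarray(fractions, float)
    n = len(fractions)
    if n < 2:
        raise ValueError("standard error undefined for fewer than 2 runs")
    return float(fractions.mean()), float(fractions.std(ddof=1) / np.sqrt(n))


def summarize_consensus(
    runs: list[ClassificationRun],
    category: str = "swapped",
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    consistency_threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> ConsensusSummary:
    """Mean ± s.e. category fraction over the consistent in-range runs.

    A run inside ``k_range`` is *consistent* when its matched fraction
    exceeds ``consistency_threshold`` against at least half of the other
    in-range runs with the same k (co-migration is only defined between runs
    with equal class counts).  Raises when fewer than two runs qualify.
    """
    k_min, k_max = k_range
    in_range = [r for r in runs if k_min <= r.k <= k_max]
    if len(in_range) < 2:
        raise ValueError(
            f"need >= 2 runs with k in [{k_min}, {k_max}] (got {len(in_range)})"
        )
    comigration: dict[tuple[object, object], float] = {}
    partners: dict[object, list[object]] = {r.run_id: [] for r in in_range}
    for i, ra in enumerate(in_range):
        for rb in in_range[i + 1 :]:
            if ra.k != rb.k:
                continue
            mf, _ = comigration_matched_fraction(ra, rb)
            comigration[(ra.run_id, rb.run_id)] = mf
            comigration[(rb.run_id, ra.run_id)] = mf
            partners[ra.run_id].append(rb.run_id)
            partners[rb.run_id].append(ra.run_id)

    consistent = []
    for r in in_range:
        mates = partners[r.run_id]
        if not mates:
            continue
        n_good = sum(
            1 for m in mates if comigration[(r.run_id, m)] > consistency_threshold
        )
        if n_good >= len(mates) / 2:
            consistent.append(r)
    if len(consistent) < 2:
        raise ValueError(
            f"fewer than 2 consistent runs (threshold {consistency_threshold}); "
            "standard error undefined"
        )
    fractions = {r.run_id: category_fraction(r, category) for r in in_range}
    mean, sem = consensus_stats(
        np.array([fractions[r.run_id] for r in consistent])
    )
    return ConsensusSummary(
        per_run_fraction=fractions,
        comigration=comigration,
        consistent_runs=[r.run_id for r in consistent],
        mean=mean,
        sem=sem,
        n=len(consistent),
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_runs_csv(
    labels_path: str | Path, categories_path: str | Path
) -> list[ClassificationRun]:
    """Assemble runs from two CSVs.

    ``labels_path`` columns: particle_id, run_id, class_id (one row per
    particle per run).  ``categories_path`` columns: run_id, class_id,
    category.  k is the number of annotated classes of each run.
    """
    labels = pd.read_csv(labels_path)
    cats = pd.read_csv(categories_path)
    for col in ("particle_id", "run_id", "class_id"):
        if col not in labels.columns:
            raise ValueError(f"{labels_path}: missing column {col!r}")
    for col in ("run_id", "class_id", "category"):
        if col not in cats.columns:
            raise ValueError(f"{categories_path}: missing column {col!r}")
    runs = []
    for run_id, group in labels.groupby("run_id", sort=True):
        run_cats = cats[cats["run_id"] == run_id]
        categories = dict(zip(run_cats["class_id"], run_cats["category"]))
        runs.append(
            ClassificationRun(
                run_id=str(run_id),
                k=len(categories),
                labels=dict(zip(group["particle_id"], group["class_id"])),
                class_categories=categories,
            )
        )
    return runs


def summary_to_frame(summary: ConsensusSummary) -> pd.DataFrame:
    """Flatten a summary into a per-run table with the headline statistics."""
    rows = [
        {
            "run_id": run_id,
            "fraction": frac,
            "consistent": run_id in summary.consistent_runs,
            "mean": summary.mean,
            "sem": summary.sem,
            "n": summary.n,
        }
        for run_id, frac in sorted(summary.per_run_fraction.items())
    ]
    return pd.DataFrame(rows)
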