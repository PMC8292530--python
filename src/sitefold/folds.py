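"""Cross-validation fold construction for multi-site cohorts.

Three fold schemes are provided:

* **preserved-site folds** — every tissue-submitting site is isolated to a
  single fold.  Fold membership is the binary matrix ``m[s, c]`` (site s in
  fold c) chosen to minimize the squared divergence from perfect outcome
  stratification,

      error = sum_{f, c} ( sum_s m[s, c] n[s, f]  -  sum_s n[s, f] / k )^2

  subject to sum_c m[s, c] = 1 for every site, where ``n[s, f]`` counts the
  patients of site s in outcome class f.  Small instances (by default up to
  15 sites) are solved to proven global optimality with a deterministic
  branch-and-bound (per-class water-filling relaxation as the lower bound,
  fold-symmetry breaking); larger instances fall back to a seeded
  multi-start local search and are flagged as heuristic.
* **standard folds** — patient-level stratified k-fold ignoring site.
* **site-balanced folds** — every site spread evenly over all folds (the
  scheme for site-prediction experiments).

Patients are the optimization unit; slides follow their patient.  Patients
with a missing outcome do not enter the count matrix but follow their site
into its fold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .manifest import MISSING, CATEGORICAL, CohortManifest, OutcomeColumn

__all__ = [
    "SiteClassCounts",
    "FoldSpec",
    "FoldAssignment",
    "build_counts",
    "bin_continuous",
    "stratification_error",
    "preserved_folds",
    "brute_force_folds",
    "standard_folds",
    "site_balanced_folds",
]


@dataclass
class SiteClassCounts:
    """Patients per site per outcome class (the n[s, f] matrix)."""

    n: np.ndarray
    site_ids: list[str]
    class_labels: list[str]
    #: patients excluded from n for missing outcome, grouped by site
    missing_by_site: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if self.n.ndim != 2 or not np.issubdtype(self.n.dtype, np.integer):
            raise ValueError("n must be a 2-D integer matrix")
        if np.any(self.n < 0):
            raise ValueError("counts must be non-negative")
        if self.n.shape != (len(self.site_ids), len(self.class_labels)):
            raise ValueError("n shape does not match site/class labels")

    @property
    def class_totals(self) -> np.ndarray:
        return self.n.sum(axis=0)


@dataclass
class FoldSpec:
    """Fold construction parameters."""

    k: int = 3
    seed: int = 0
    exact_threshold: int = 15  # sites up to this count are solved exactly
    restarts: int = 1000  # local-search restarts beyond the threshold

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class FoldAssignment:
    """A site-to-fold map with its stratification error."""

    m: np.ndarray  # sites x k binary
    error: float
    optimal: bool
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if not np.all(self.m.sum(axis=1) == 1):
            raise ValueError("every site must belong to exactly one fold")

    @property
    def k(self) -> int:
        return self.m.shape[1]

    def fold_of_site(self) -> dict[str, int]:
        return {s: int(np.argmax(self.m[i])) for i, s in enumerate(self.site_ids)}

    def patient_folds(self, manifest: CohortManifest) -> dict[str, int]:
        """Map every patient (including missing-outcome ones) to its site's fold."""
        site_fold = self.fold_of_site()
        return {p: site_fold[s] for p, s in manifest.site_of_patient().items()}


# ---------------------------------------------------------------------------
# Count matrix construction


def build_counts(manifest: CohortManifest, outcome: str) -> SiteClassCounts:
    """Patients (not slides) per site per class for one categorical outcome."""
    if manifest.column(outcome).kind != CATEGORICAL:
        raise ValueError(
            f"outcome {outcome!r} is continuous; bin it first (bin_continuous)"
        )
    patient_value = manifest.patient_outcome(outcome)
    site_of = manifest.site_of_patient()
    sites = manifest.site_ids
    classes = sorted({v for v in patient_value.values() if v is not MISSING})
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 observed classes")
    n = np.zeros((len(sites), len(classes)), dtype=np.int64)
    s_idx = {s: i for i, s in enumerate(sites)}
    c_idx = {c: j for j, c in enumerate(classes)}
    missing: dict[str, list[str]] = {}
    for patient, value in patient_value.items():
        if value is MISSING:
            missing.setdefault(site_of[patient], []).append(patient)
        else:
            n[s_idx[site_of[patient]], c_idx[value]] += 1
    return SiteClassCounts(n, list(sites), [str(c) for c in classes], missing)


def bin_continuous(
    manifest: CohortManifest, outcome: str, n_bins: int = 4
) -> CohortManifest:
    """Append a quantile-binned categorical copy of a continuous outcome.

    Patients are ranked by (value, patient id) and split into ``n_bins``
    near-equal groups, the quartile default mirroring the practice of
    stratifying a continuous feature into quartiles before optimization.
    Fewer distinct values than bins reduces the bin count with a warning.
    """
    col = manifest.column(outcome)
    if col.kind == CATEGORICAL:
        raise ValueError(f"outcome {outcome!r} is already categorical")
    values = {
        p: v for p, v in manifest.patient_outcome(outcome).items() if v is not MISSING
    }
    distinct = len(set(values.values()))
    if distinct < n_bins:
        warnings.warn(
            f"only {distinct} distinct values; reducing bins {n_bins} -> {max(1, distinct)}",
            stacklevel=2,
        )
        n_bins = max(1, distinct)
    ranked = sorted(values, key=lambda p: (values[p], p))
    labels: dict[str, str] = {}
    for b, chunk in enumerate(np.array_split(ranked, n_bins)):
        for p in chunk:
            labels[p] = f"q{b + 1}"
    return manifest.with_column(OutcomeColumn(f"{outcome}_bin", CATEGORICAL), labels)


# ---------------------------------------------------------------------------
# Stratification error (the optimization objective)


def stratification_error(m: np.ndarray, counts: SiteClassCounts, k: int) -> float:
    """Squared divergence of per-fold class totals from the ideal 1/k share."""
    m = np.asarray(m)
    if m.shape != (counts.n.shape[0], k):
        raise ValueError(f"m has shape {m.shape}, expected ({counts.n.shape[0]}, {k})")
    if not np.all(m.sum(axis=1) == 1):
        raise ValueError("constraint violated: each site must be in exactly one fold")
    fold_totals = m.T.astype(np.float64) @ counts.n  # k x F
    target = counts.class_totals / k
    return float(((fold_totals - target) ** 2).sum())


# ---------------------------------------------------------------------------
# Exact solver: branch and bound


def _class_lower_bound(t: np.ndarray, total: float, k: int) -> float:
    """min sum_c (y_c - total/k)^2 over y >= t, sum y = total (water filling)."""
    target = total / k
    # y_c = max(t_c, theta) with theta solving sum max(t_c, theta) = total
    order = np.sort(t)
    csum = np.cumsum(order)
    theta = None
    for i in range(k):
        # candidate: folds 0..i raised to theta, the rest stay at t
        cand = (total - (csum[-1] - csum[i])) / (i + 1)
        if cand <= (order[i + 1] if i + 1 < k else np.inf) + 1e-12:
            theta = cand
            break
    if theta is None:  # numerically unreachable; fall back to relaxed bound
        theta = total / k
    y = np.maximum(order, theta)
    # renormalize tiny drift
    return float(((y - target) ** 2).sum())


def _lower_bound(fold_sums: np.ndarray, remaining: np.ndarray, totals: np.ndarray, k: int) -> float:
    lb = 0.0
    for f in range(totals.size):
        if remaining[f] == 0:
            lb += float(((fold_sums[:, f] - totals[f] / k) ** 2).sum())
        else:
            lb += _class_lower_bound(fold_sums[:, f].astype(np.float64), float(totals[f]), k)
    return lb


def _branch_and_bound(n: np.ndarray, k: int, incumbent_m: np.ndarray, incumbent_err: float):
    """Exact minimization of the stratification error via DFS with pruning.

    Sites are assumed pre-sorted by descending total.  Fold symmetry is
    broken by allowing a site into at most one currently-empty fold.
    """
    S, F = n.shape
    totals = n.sum(axis=0).astype(np.float64)
    target = totals / k
    suffix_remaining = np.vstack([n[i:].sum(axis=0) for i in range(S)] + [np.zeros(F, dtype=n.dtype)])

    best_m = incumbent_m.copy()
    best_err = incumbent_err
    assign = np.full(S, -1, dtype=np.int64)
    fold_sums = np.zeros((k, F), dtype=np.float64)
    fold_count = np.zeros(k, dtype=np.int64)

    def rec(i: int, used: int) -> None:
        nonlocal best_m, best_err
        if i == S:
            err = float(((fold_sums - target) ** 2).sum())
            if err < best_err - 1e-12:
                best_err = err
                m = np.zeros((S, k), dtype=np.int64)
                m[np.arange(S), assign] = 1
                best_m = m
            return
        # feasibility: enough sites left to populate empty folds
        if S - i < k - used:
            return
        lb = _lower_bound(fold_sums, suffix_remaining[i], totals, k)
        if lb >= best_err - 1e-12:
            return
        limit = min(used + 1, k)
        for c in range(limit):
            assign[i] = c
            fold_sums[c] += n[i]
            fold_count[c] += 1
            rec(i + 1, used + (1 if c == used else 0))
            fold_count[c] -= 1
            fold_sums[c] -= n[i]
            assign[i] = -1

    rec(0, 0)
    return best_m, best_err


# ---------------------------------------------------------------------------
# Heuristic solver: seeded greedy + local search


def _greedy_assignment(n: np.ndarray, k: int, order: np.ndarray, target: np.ndarray) -> np.ndarray:
    S = n.shape[0]
    assign = np.full(S, -1, dtype=np.int64)
    fold_sums = np.zeros((k, n.shape[1]), dtype=np.float64)
    fold_count = np.zeros(k, dtype=np.int64)
    for pos, i in enumerate(order):
        remaining_after = S - pos - 1
        best_c, best_delta = 0, np.inf
        for c in range(k):
            empties_other = int((fold_count == 0).sum()) - (1 if fold_count[c] == 0 else 0)
            if remaining_after < empties_other:
                continue  # must keep enough sites for still-empty folds
            delta = (((fold_sums[c] + n[i]) - target) ** 2).sum() - ((fold_sums[c] - target) ** 2).sum()
            if delta < best_delta:
                best_delta, best_c = delta, c
        assign[i] = best_c
        fold_sums[best_c] += n[i]
        fold_count[best_c] += 1
    return assign


def _local_search(n: np.ndarray, k: int, assign: np.ndarray, target: np.ndarray) -> np.ndarray:
    S = n.shape[0]
    fold_sums = np.zeros((k, n.shape[1]), dtype=np.float64)
    for i in range(S):
        fold_sums[assign[i]] += n[i]

    def err_of(sums: np.ndarray) -> float:
        return float(((sums - target) ** 2).sum())

    current = err_of(fold_sums)
    improved = True
    while improved:
        improved = False
        # single-site moves
        for i in range(S):
            c0 = assign[i]
            if (assign == c0).sum() == 1:
                continue  # would empty a fold
            for c1 in range(k):
                if c1 == c0:
                    continue
                trial = fold_sums.copy()
                trial[c0] -= n[i]
                trial[c1] += n[i]
                e = err_of(trial)
                if e < current - 1e-12:
                    fold_sums = trial
                    assign[i] = c1
                    current = e
                    improved = True
                    break
        # pairwise swaps
        for i in range(S):
            for j in range(i + 1, S):
                ci, cj = assign[i], assign[j]
                if ci == cj:
                    continue
                trial = fold_sums.copy()
                trial[ci] += n[j] - n[i]
                trial[cj] += n[i] - n[j]
                e = err_of(trial)
                if e < current - 1e-12:
                    fold_sums = trial
                    assign[i], assign[j] = cj, ci
                    current = e
                    improved = True
    return assign


def _heuristic(n: np.ndarray, k: int, restarts: int, seed: int) -> tuple[np.ndarray, float]:
    S, F = n.shape
    totals = n.sum(axis=0).astype(np.float64)
    target = totals / k
    rng = np.random.default_rng(seed)
    best_assign, best_err = None, np.inf
    for r in range(restarts):
        order = np.argsort(-n.sum(axis=1), kind="stable") if r == 0 else rng.permutation(S)
        assign = _greedy_assignment(n, k, order, target)
        assign = _local_search(n, k, assign, target)
        fold_sums = np.zeros((k, F), dtype=np.float64)
        for i in range(S):
            fold_sums[assign[i]] += n[i]
        err = float(((fold_sums - target) ** 2).sum())
        if err < best_err - 1e-12:
            best_err, best_assign = err, assign.copy()
            if best_err < 1e-12:
                break
    m = np.zeros((S, k), dtype=np.int64)
    m[np.arange(S), best_assign] = 1
    return m, best_err


# ---------------------------------------------------------------------------
# Public solvers


def preserved_folds(counts: SiteClassCounts, spec: FoldSpec) -> FoldAssignment:
    """Assign each site to one of k folds minimizing the stratification error.

    Up to ``spec.exact_threshold`` sites, the returned error is the proven
    global optimum (branch and bound); beyond, a seeded multi-start local
    search is used and ``optimal`` is False.  Every fold receives at least
    one site.  Deterministic given the spec seed.
    """
    S = counts.n.shape[0]
    if S < spec.k:
        raise ValueError(f"{S} sites cannot fill {spec.k} folds")
    # pre-sort sites by descending total for tie-break determinism and pruning
    order = np.argsort(-counts.n.sum(axis=1), kind="stable")
    n_sorted = counts.n[order]

    if S <= spec.exact_threshold:
        m0, e0 = _heuristic(n_sorted, spec.k, restarts=32, seed=spec.seed)
        m_sorted, err = _branch_and_bound(n_sorted, spec.k, m0, e0 + 1e-9)
        optimal = True
    else:
        m_sorted, err = _heuristic(n_sorted, spec.k, restarts=spec.restarts, seed=spec.seed)
        optimal = False

    m = np.zeros_like(m_sorted)
    m[order] = m_sorted
    err = stratification_error(m, counts, spec.k)  # recompute in original order
    return FoldAssignment(m=m, error=err, optimal=optimal, site_ids=list(counts.site_ids))


def brute_force_folds(counts: SiteClassCounts, spec: FoldSpec) -> FoldAssignment:
    """Exhaustive-enumeration optimum (test oracle for the main solver).

    Fold symmetry is reduced by fixing site 0 to fold 0; ties are broken
    lexicographically on the flattened m.  Instances with k^(sites-1) above
    ten million are refused.
    """
    S = counts.n.shape[0]
    k = spec.k
    if S < k:
        raise ValueError(f"{S} sites cannot fill {k} folds")
    if k ** (S - 1) > 10_000_000:
        raise ValueError(
            f"instance too large for exhaustive search (k^(S-1) = {k ** (S - 1)}); "
            "use preserved_folds"
        )
    n = counts.n.astype(np.float64)
    target = counts.class_totals / k
    best_err, best_m = np.inf, None
    for rest in itertools.product(range(k), repeat=S - 1):
        assign = (0,) + rest
        if len(set(assign)) < k:
            continue  # an empty fold is not a usable CV split
        fold_sums = np.zeros((k, n.shape[1]))
        for i, c in enumerate(assign):
            fold_sums[c] += n[i]
        err = float(((fold_sums - target) ** 2).sum())
        if err < best_err - 1e-12:
            best_err = err
            best_m = assign
        elif best_m is not None and abs(err - best_err) <= 1e-12:
            if assign < best_m:
                best_m = assign
    m = np.zeros((S, k), dtype=np.int64)
    m[np.arange(S), np.asarray(best_m)] = 1
    return FoldAssignment(m=m, error=best_err, optimal=True, site_ids=list(counts.site_ids))


# ---------------------------------------------------------------------------
# Non-preserved schemes


def _deal_round_robin(
    items: list[str], k: int, rng: np.random.Generator, folds: dict[str, int]
) -> None:
    shuffled = list(items)
    rng.shuffle(shuffled)
    for idx, item in enumerate(shuffled):
        folds[item] = idx % k


def standard_folds(
    manifest: CohortManifest, outcome: str, k: int = 3, seed: int = 0
) -> dict[str, int]:
    """Patient-level stratified k-fold ignoring site.

    Per outcome class, patients are shuffled (seeded) and dealt round-robin,
    so fold class proportions agree with the cohort within one patient.
    Missing-outcome patients are dealt as their own group.
    """
    patient_value = manifest.patient_outcome(outcome)
    rng = np.random.default_rng(seed)
    by_class: dict[object, list[str]] = {}
    for p in manifest.patient_ids:
        by_class.setdefault(patient_value.get(p, MISSING), []).append(p)
    folds: dict[str, int] = {}
    for cls in sorted(by_class, key=lambda c: (c is MISSING, str(c))):
        members = by_class[cls]
        if cls is not MISSING and len(members) < k:
            warnings.warn(
                f"class {cls!r} has only {len(members)} patients for {k} folds",
                stacklevel=2,
            )
        _deal_round_robin(members, k, rng, folds)
    return folds


def site_balanced_folds(
    manifest: CohortManifest, k: int = 3, seed: int = 0
) -> dict[str, int]:
    """Each site represented (near-)equally in every fold.

    Within each site, patients are shuffled (seeded) and dealt round-robin
    across folds — the splitting scheme for site-prediction experiments.
    """
    rng = np.random.default_rng(seed)
    by_site: dict[str, list[str]] = {}
    site_of = manifest.site_of_patient()
    for p in manifest.patient_ids:
        by_site.setdefault(site_of[p], []).append(p)
    folds: dict[str, int] = {}
    for site in sorted(by_site):
        members = by_site[site]
        if len(members) < k:
            warnings.warn(
                f"site {site!r} has only {len(members)} patients for {k} folds",
                stacklevel=2,
            )
        _deal_round_robin(members, k, rng, folds)
    return folds
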