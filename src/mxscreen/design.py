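"""Penalty-guided all-pairs covering designs for pooled combination screens.

A pooled combination screen places ``n`` compounds from a library of ``N``
into each well so that every unordered compound pair co-occurs in at least
one well, with the well count ``m`` kept near the counting lower bound
``ceil(C(N,2) / C(n,2))``.  Exact minimum covers are only tractable for tiny
libraries, so the search here is heuristic: every pair starts with a random
penalty, candidate wells are sampled (each seeded with a not-yet-covered
pair so progress is guaranteed), the candidate with the smallest summed
pair penalty is accepted, its pairs leave the active list and their
penalties are incremented to steer later wells away from re-used pairs.
The whole search is restarted from fresh random penalties several times and
the best run kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, StateExhaustedError

__all__ = [
    "CompoundLibrary",
    "CompoundPair",
    "PenaltyState",
    "WellAssignment",
    "ScreenDesign",
    "CoverageReport",
    "CalibrationResult",
    "enumerate_pairs",
    "well_pairs",
    "well_penalty",
    "propose_well",
    "design_screen",
    "verify_coverage",
    "calibrate",
]

DEFAULT_RESTARTS = 50
DEFAULT_TRIALS = 1000
PENALTY_INCREMENT = 1.0


@dataclass(frozen=True)
class CompoundPair:
    """An unordered compound pair in canonical (library-order) orientation."""

    first: str
    second: str

    def __iter__(self):
        return iter((self.first, self.second))


class CompoundLibrary:
    """An ordered collection of unique compound identifiers.

    The ordering is significant: it defines the canonical orientation of
    every :class:`CompoundPair` and the pair enumeration order.
    """

    def __init__(self, compounds: Sequence[str]):
        compounds = tuple(str(c) for c in compounds)
        if len(compounds) < 2:
            raise InvalidInputError(
                f"a compound library needs at least 2 compounds, got {len(compounds)}"
            )
        if len(set(compounds)) != len(compounds):
            dupes = sorted({c for c in compounds if compounds.count(c) > 1})
            raise InvalidInputError(f"duplicate compound identifiers: {dupes}")
        self.compounds: tuple[str, ...] = compounds
        self._index = {c: i for i, c in enumerate(compounds)}

    @property
    def size(self) -> int:
        return len(self.compounds)

    @property
    def n_pairs(self) -> int:
        N = self.size
        return N * (N - 1) // 2

    def index(self, compound: str) -> int:
        try:
            return self._index[compound]
        except KeyError:
            raise InvalidInputError(f"unknown compound: {compound!r}") from None

    def pair(self, a: str, b: str) -> CompoundPair:
        """Canonically oriented pair of two distinct library compounds."""
        ia, ib = self.index(a), self.index(b)
        if ia == ib:
            raise InvalidInputError(f"a pair needs two distinct compounds, got {a!r} twice")
        if ia > ib:
            a, b = b, a
        return CompoundPair(a, b)

    def pair_index(self, pair: CompoundPair) -> int:
        """Position of ``pair`` in the canonical enumeration order."""
        i, j = self.index(pair.first), self.index(pair.second)
        if i > j:
            i, j = j, i
        return condensed_index(np.asarray(i), np.asarray(j), self.size).item()

    def pair_from_index(self, k: int) -> CompoundPair:
        i, j = _index_to_pair(k, self.size)
        return CompoundPair(self.compounds[i], self.compounds[j])

    def __len__(self) -> int:
        return self.size

    def __contains__(self, compound: str) -> bool:
        return compound in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, CompoundLibrary) and self.compounds == other.compounds

    def __repr__(self) -> str:
        return f"CompoundLibrary(N={self.size})"


def condensed_index(i: np.ndarray, j: np.ndarray, N: int) -> np.ndarray:
    """Map compound index pairs (i < j) to condensed pair indices.

    Pairs are enumerated (0,1), (0,2), ..., (0,N-1), (1,2), ... so the
    condensed order equals enumeration by library order.
    """
    return i * (2 * N - i - 1) // 2 + (j - i - 1)


def _index_to_pair(k: int, N: int) -> tuple[int, int]:
    # invert the condensed index; N is small enough for a linear scan per row
    i = 0
    row = N - 1
    while k >= row:
        k -= row
        i += 1
        row -= 1
    return i, i + 1 + k


def enumerate_pairs(library: CompoundLibrary) -> list[CompoundPair]:
    """All N(N-1)/2 canonical pairs, ordered by library order."""
    comps = library.compounds
    return [
        CompoundPair(comps[i], comps[j])
        for i in range(len(comps))
        for j in range(i + 1, len(comps))
    ]


@dataclass(frozen=True)
class WellAssignment:
    """One screen well: an integer id plus its set of member compounds.

    Members are stored as a tuple sorted by library order so designs are
    byte-stable and exports deterministic.
    """

    well_id: int
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def well_pairs(well: WellAssignment, library: CompoundLibrary) -> list[CompoundPair]:
    """The n(n-1)/2 pairs induced by the well's members, canonically oriented."""
    if well.size < 2:
        raise InvalidInputError(
            f"well {well.well_id} has {well.size} member(s); pairs need at least 2"
        )
    idx = sorted(library.index(c) for c in well.members)
    comps = library.compounds
    return [
        CompoundPair(comps[idx[a]], comps[idx[b]])
        for a in range(len(idx))
        for b in range(a + 1, len(idx))
    ]


class PenaltyState:
    """Per-pair penalties plus the active (not-yet-covered) pair list.

    Internally a condensed penalty vector indexed by canonical pair order,
    mirrored into a symmetric N x N matrix for fast candidate growth;
    ``penalty_of`` / ``active_pairs`` expose the map/set view.
    """

    def __init__(self, library: CompoundLibrary, rng: np.random.Generator):
        self.library = library
        N = library.size
        # uniform (0,1) initial penalties; strictly positive so no candidate
        # is free before any well has been accepted
        self.penalties = rng.uniform(0.0, 1.0, size=library.n_pairs)
        self.active = np.ones(library.n_pairs, dtype=bool)
        self._ii, self._jj = np.triu_indices(N, k=1)
        self._square = np.zeros((N, N))
        self._square[self._ii, self._jj] = self.penalties
        self._square[self._jj, self._ii] = self.penalties

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def penalty_of(self, pair: CompoundPair) -> float:
        return float(self.penalties[self.library.pair_index(pair)])

    def is_active(self, pair: CompoundPair) -> bool:
        return bool(self.active[self.library.pair_index(pair)])

    def active_pairs(self) -> list[CompoundPair]:
        return [self.library.pair_from_index(int(k)) for k in np.flatnonzero(self.active)]

    def mark_covered(self, pair_idx: np.ndarray) -> None:
        """Retire covered pairs and escalate their penalties."""
        self.active[pair_idx] = False
        self.penalties[pair_idx] += PENALTY_INCREMENT
        i = self._ii[pair_idx]
        j = self._jj[pair_idx]
        self._square[i, j] += PENALTY_INCREMENT
        self._square[j, i] += PENALTY_INCREMENT


def _member_pair_indices(member_idx: np.ndarray, N: int) -> np.ndarray:
    """Condensed pair indices induced by one well's member indices."""
    a, b = np.triu_indices(len(member_idx), k=1)
    i = member_idx[a]
    j = member_idx[b]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return condensed_index(lo, hi, N)


def well_penalty(candidate: Iterable[str], state: PenaltyState) -> float:
    """Sum of current penalties over the pairs induced by a candidate well."""
    members = list(candidate)
    if len(set(members)) != len(members):
        raise InvalidInputError("candidate well contains repeated compounds")
    idx = np.array([state.library.index(c) for c in members])
    if len(idx) < 2:
        raise InvalidInputError("candidate well needs at least 2 compounds")
    return float(state.penalties[_member_pair_indices(idx, state.library.size)].sum())


def _sample_candidates(
    state: PenaltyState, n: int, trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``trials`` candidate wells of ``n`` compounds each.

    Every candidate is seeded with one uniformly drawn active pair (so any
    accepted well covers at least one uncovered pair) and grown to size n
    by penalty-greedy completion: at each step the compound whose pairs
    with the current members carry the smallest summed penalty joins the
    well.  Each candidate is therefore a local minimum of the penalty
    score given its seed pair; diversity comes from the random seeds and
    the random initial penalties.  Returns an int array (trials, n) of
    compound indices.
    """
    N = state.library.size
    active_idx = np.flatnonzero(state.active)
    seeds = active_idx[rng.integers(0, len(active_idx), size=trials)]
    members = np.empty((trials, n), dtype=np.int64)
    members[:, 0] = state._ii[seeds]
    members[:, 1] = state._jj[seeds]
    if n == 2:
        return members
    P = state._square
    rows = np.arange(trials)
    # cost[t, c] = added penalty if compound c joins candidate t now
    cost = P[members[:, 0]] + P[members[:, 1]]
    cost[rows, members[:, 0]] = np.inf
    cost[rows, members[:, 1]] = np.inf
    for k in range(2, n):
        nxt = np.argmin(cost, axis=1)
        members[:, k] = nxt
        cost += P[nxt]
        cost[rows, nxt] = np.inf
    return members


def _score_candidates(members: np.ndarray, penalties: np.ndarray, N: int) -> np.ndarray:
    """Summed pair penalties for a (trials, n) block of candidate wells."""
    n = members.shape[1]
    scores = np.zeros(members.shape[0])
    for a in range(n):
        for b in range(a + 1, n):
            i = members[:, a]
            j = members[:, b]
            lo = np.minimum(i, j)
            hi = np.maximum(i, j)
            scores += penalties[condensed_index(lo, hi, N)]
    return scores


def propose_well(
    state: PenaltyState,
    library: CompoundLibrary,
    n: int,
    trials: int = DEFAULT_TRIALS,
    rng: np.random.Generator | None = None,
) -> WellAssignment:
    """Best-of-``trials`` candidate well under the current penalties.

    Ties are broken in favour of the earliest sampled candidate.  The
    returned well always covers at least one active pair (candidates are
    seeded from the active list); ``well_id`` is assigned by the caller and
    left at -1 here.
    """
    if rng is None:
        rng = np.random.default_rng()
    if state.n_active == 0:
        raise StateExhaustedError("all pairs are already covered")
    if trials < 1:
        raise InvalidInputError(f"trials must be >= 1, got {trials}")
    if not 2 <= n <= library.size:
        raise InvalidInputError(f"compounds per well must be in [2, N={library.size}], got {n}")
    members = _sample_candidates(state, n, trials, rng)
    scores = _score_candidates(members, state.penalties, library.size)
    best = int(np.argmin(scores))  # argmin returns the earliest minimum
    member_idx = np.sort(members[best])
    return WellAssignment(-1, tuple(library.compounds[i] for i in member_idx))


@dataclass
class ScreenDesign:
    """A full all-pairs screen design plus the parameters that produced it."""

    library: CompoundLibrary
    n_per_well: int
    wells: list[WellAssignment]
    seed: int
    restarts: int = DEFAULT_RESTARTS
    trials: int = DEFAULT_TRIALS

    @property
    def m(self) -> int:
        """Number of wells."""
        return len(self.wells)

    @property
    def pair_slots(self) -> int:
        """Total pair slots m * n(n-1)/2 across all wells."""
        return sum(w.size * (w.size - 1) // 2 for w in self.wells)

    @property
    def redundancy(self) -> float:
        """Pair slots divided by unique pairs covered (>= 1 for full coverage)."""
        covered = len({(p.first, p.second) for w in self.wells for p in well_pairs(w, self.library)})
        return self.pair_slots / covered


def _run_once(
    library: CompoundLibrary, n: int, trials: int, rng: np.random.Generator
) -> list[WellAssignment]:
    """One covering run: propose wells until the active list empties."""
    state = PenaltyState(library, rng)
    wells: list[WellAssignment] = []
    N = library.size
    while state.n_active > 0:
        well = propose_well(state, library, n, trials, rng)
        member_idx = np.array([library.index(c) for c in well.members])
        state.mark_covered(_member_pair_indices(member_idx, N))
        wells.append(WellAssignment(len(wells), well.members))
    return wells


def design_screen(
    library: CompoundLibrary,
    n: int,
    restarts: int = DEFAULT_RESTARTS,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
) -> ScreenDesign:
    """Search for a near-minimal all-pairs design.

    Runs the penalty-guided covering search ``restarts`` times from fresh
    random penalties and returns the run with the fewest wells (ties:
    lower redundancy, then earlier restart).  Fully reproducible from
    ``seed``: restart r uses the r-th child of ``SeedSequence(seed)``.
    """
    if not 2 <= n <= library.size:
        raise InvalidInputError(
            f"compounds per well must be in [2, N={library.size}], got {n}"
        )
    if restarts < 1:
        raise InvalidInputError(f"restarts must be >= 1, got {restarts}")
    children = np.random.SeedSequence(seed).spawn(restarts)
    best: ScreenDesign | None = None
    best_key: tuple[int, float, int] | None = None
    for r, child in enumerate(children):
        wells = _run_once(library, n, trials, np.random.default_rng(child))
        cand = ScreenDesign(library, n, wells, seed=seed, restarts=restarts, trials=trials)
        key = (cand.m, cand.redundancy, r)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    assert best is not None
    return best


@dataclass
class CoverageReport:
    """Result of auditing a design against the all-pairs requirement."""

    n_pairs: int
    covered: int
    missing: list[CompoundPair]
    redundancy: float
    usage: dict[str, int]

    @property
    def complete(self) -> bool:
        return not self.missing


def verify_coverage(design: ScreenDesign) -> CoverageReport:
    """Audit pair coverage, redundancy and per-compound usage of a design."""
    lib = design.library
    hit = np.zeros(lib.n_pairs, dtype=np.int64)
    usage: dict[str, int] = {c: 0 for c in lib.compounds}
    slots = 0
    for well in design.wells:
        for c in well.members:
            if c not in lib:
                raise InvalidInputError(
                    f"well {well.well_id} references unknown compound {c!r}"
                )
            usage[c] += 1
        member_idx = np.array([lib.index(c) for c in well.members])
        pidx = _member_pair_indices(member_idx, lib.size)
        hit[pidx] += 1
        slots += len(pidx)
    covered = int((hit > 0).sum())
    missing = [lib.pair_from_index(int(k)) for k in np.flatnonzero(hit == 0)]
    redundancy = slots / covered if covered else float("inf")
    return CoverageReport(lib.n_pairs, covered, missing, redundancy, usage)


def counting_lower_bound(N: int, n: int) -> int:
    """ceil(C(N,2) / C(n,2)): no design can use fewer wells."""
    return -((N * (N - 1) // 2) // -(n * (n - 1) // 2))


@dataclass
class CalibrationResult:
    """Well usage across a grid of library sizes N and pool sizes n.

    ``runs`` holds one row per (N, n, iteration) with the achieved well
    count; ``medians`` the per-cell median m; ``rates`` the change in
    median m when n increases by one step at fixed N.
    """

    runs: pd.DataFrame
    medians: pd.DataFrame
    rates: pd.DataFrame

    def median_m(self, N: int, n: int) -> float:
        sel = self.medians[(self.medians["N"] == N) & (self.medians["n"] == n)]
        if sel.empty:
            raise InvalidInputError(f"no calibration cell for N={N}, n={n}")
        return float(sel["median_m"].iloc[0])


def calibrate(
    N_values: Sequence[int],
    n_values: Sequence[int],
    iterations: int = 5,
    seed: int = 0,
    restarts: int = 10,
    trials: int = 500,
    compound_prefix: str = "C",
) -> CalibrationResult:
    """Map well usage m over a grid of (N, n).

    Each cell runs the covering search ``iterations`` times under distinct
    seeds (children of ``SeedSequence(seed)``) and records the achieved
    well count; the per-cell summary is the median, matching how well
    usage is conventionally reported for stochastic covering searches.
    Cells with n > N (or n < 2) are skipped with a warning.
    """
    if iterations < 1:
        raise InvalidInputError(f"iterations must be >= 1, got {iterations}")
    root = np.random.SeedSequence(seed)
    rows = []
    cell = 0
    for N in N_values:
        library = CompoundLibrary([f"{compound_prefix}{i:03d}" for i in range(N)])
        for n in n_values:
            if n < 2 or n > N:
                warnings.warn(f"skipping incompatible calibration cell N={N}, n={n}")
                cell += 1
                continue
            for it in range(iterations):
                # stable per-cell/iteration seed stream regardless of skips
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(cell, it)
                )
                sub_seed = int(child.generate_state(1)[0] % (2**31))
                design = design_screen(library, n, restarts=restarts, trials=trials, seed=sub_seed)
                rows.append({"N": N, "n": n, "iteration": it, "m": design.m})
            cell += 1
    runs = pd.DataFrame(rows, columns=["N", "n", "iteration", "m"])
    if runs.empty:
        raise InvalidInputError("no compatible (N, n) calibration cells")
    medians = (
        runs.groupby(["N", "n"], as_index=False)["m"].median().rename(columns={"m": "median_m"})
    )
    rates = medians.sort_values(["N", "n"]).copy()
    rates["delta_m"] = rates.groupby("N")["median_m"].diff()
    rates["delta_n"] = rates.groupby("N")["n"].diff()
    rates = rates.dropna(subset=["delta_m"]).reset_index(drop=True)
    return CalibrationResult(runs=runs, medians=medians, rates=rates)
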