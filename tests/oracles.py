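"""Independent brute-force oracles used to validate the heuristic search.

Kept free of any mxscreen search code: the covering optimum is found by
exhaustive branch-and-bound over all candidate wells, feasible for tiny
libraries (N <= 7 or so).
"""

from itertools import combinations


def exact_min_wells(N: int, n: int) -> int:
    """Minimum number of n-compound wells covering all C(N,2) pairs.

    Iterative deepening from the counting lower bound; branches on the
    lowest-index uncovered pair, trying every candidate well that covers
    it.  Exact for small N.
    """
    pairs = list(combinations(range(N), 2))
    bit = {p: 1 << k for k, p in enumerate(pairs)}
    full = (1 << len(pairs)) - 1
    wells = []
    for members in combinations(range(N), n):
        mask = 0
        for p in combinations(members, 2):
            mask |= bit[p]
        wells.append(mask)

    def dfs(cov: int, depth: int, budget: int) -> bool:
        if cov == full:
            return True
        if depth >= budget:
            return False
        uncovered = ~cov & full
        low = uncovered & -uncovered  # lowest uncovered pair
        for mask in wells:
            if mask & low and dfs(cov | mask, depth + 1, budget):
                return True
        return False

    per_well = n * (n - 1) // 2
    budget = max(1, -((N * (N - 1) // 2) // -per_well))
    while not dfs(0, 0, budget):
        budget += 1
    return budget
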