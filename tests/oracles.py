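"""Independent brute-force reference implementations.

Every function here recomputes a pipeline quantity by a different route
(per-voxel library calls, explicit regression, BFS flood fill, set
algebra) so the vectorized implementations can be checked against them on
seeded instances.  Nothing in this module imports the implementation paths
it is used to check.
"""

from __future__ import annotations

from collections import Counter, deque

import numpy as np
from scipy import stats


def brute_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-voxel pooled two-sample t via scipy.stats.ttest_ind."""
    out = np.full(a.shape[1:], np.nan)
    for idx in np.ndindex(*a.shape[1:]):
        xa, xb = a[(slice(None),) + idx], b[(slice(None),) + idx]
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            continue
        out[idx] = stats.ttest_ind(xa, xb, equal_var=True).statistic
    return out


def brute_interaction_map(cells: dict) -> np.ndarray:
    """Interaction t via explicit dummy-coded OLS, one fit per voxel."""
    keys = [("sham", 0), ("sham", 60), ("WAS", 0), ("WAS", 60)]
    ys, rows = [], []
    for key in keys:
        for vol in cells[key]:
            data = vol.data if hasattr(vol, "data") else np.asarray(vol)
            ys.append(data)
            was = 1.0 if key[0] == "WAS" else 0.0
            crd = 1.0 if key[1] == 60 else 0.0
            rows.append([1.0, was, crd, was * crd])
    y = np.stack(ys, axis=0)
    x = np.array(rows)
    xtx_inv = np.linalg.inv(x.T @ x)
    n, p = x.shape
    out = np.full(y.shape[1:], np.nan)
    for idx in np.ndindex(*y.shape[1:]):
        yi = y[(slice(None),) + idx]
        beta = xtx_inv @ x.T @ yi
        resid = yi - x @ beta
        sigma2 = resid @ resid / (n - p)
        if sigma2 == 0:
            continue
        out[idx] = beta[3] / np.sqrt(sigma2 * xtx_inv[3, 3])
    return out


def brute_pearson_map(x: np.ndarray, seed_values: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel Pearson r and its t statistic via scipy.stats.pearsonr."""
    r = np.full(x.shape[1:], np.nan)
    t = np.full(x.shape[1:], np.nan)
    df = len(seed_values) - 2
    for idx in np.ndindex(*x.shape[1:]):
        xi = x[(slice(None),) + idx]
        if xi.std() == 0:
            continue
        ri = stats.pearsonr(xi, seed_values).statistic
        r[idx] = ri
        ri = min(max(ri, -1.0), 1.0)
        t[idx] = ri * np.sqrt(df / max(1.0 - ri ** 2, 1e-300))
    return r, t


_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_OFFSETS[18] = _OFFSETS[6] + [
    (a, b, 0) for a in (-1, 1) for b in (-1, 1)] + [
    (a, 0, b) for a in (-1, 1) for b in (-1, 1)] + [
    (0, a, b) for a in (-1, 1) for b in (-1, 1)]
_OFFSETS[26] = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]


def brute_components(binary: np.ndarray, connectivity: int = 6
                     ) -> list[set[tuple[int, int, int]]]:
    """Connected components of a 3D binary array by BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp, queue = set(), deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in _OFFSETS[connectivity]:
                w = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= w[i] < binary.shape[i] for i in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def brute_region_overlap(cluster_voxels: np.ndarray, labels: np.ndarray
                         ) -> Counter:
    """Voxel counts per atlas label under a cluster, by explicit tally."""
    counts: Counter = Counter()
    for v in map(tuple, np.asarray(cluster_voxels)):
        counts[int(labels[v])] += 1
    return counts


def brute_slfc(fc_signs: dict[str, int], edges: set[tuple[str, str]],
               node_universe: set[str], seed: str
               ) -> tuple[dict[str, str], set[str], set[str]]:
    """Set-algebra SLFC intersection: region → direction, plus the
    FC-without-SC and unresolved-name sets."""
    result, without_sc, unresolved = {}, set(), set()
    for region, sign in fc_signs.items():
        if sign == 0 or region == seed:
            continue
        if region not in node_universe:
            unresolved.add(region)
            continue
        inward = (region, seed) in edges
        outward = (seed, region) in edges
        if inward and outward:
            result[region] = "bidirectional"
        elif inward:
            result[region] = "partner_to_seed"
        elif outward:
            result[region] = "seed_to_partner"
        else:
            without_sc.add(region)
    return result, without_sc, unresolved
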