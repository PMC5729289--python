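"""Independent brute-force reference implementations used only by tests.

Each oracle favors clarity over speed and shares no code with the package
paths it checks: GTOM by explicit BFS neighborhoods and set intersections,
module scoring by per-sample Python loops, and Cox fitting by grid search
over the Efron partial likelihood.
"""

import math

import networkx as nx
import numpy as np

from ppisig.network import PPINetwork


def gtom_bfs_oracle(network: PPINetwork, m: int) -> np.ndarray:
    """GTOM by materialized m-step BFS neighborhoods and set intersections."""
    nodes = network.nodes
    g = network.graph
    nbhd = {}
    for v in nodes:
        reach = nx.single_source_shortest_path_length(g, v, cutoff=m)
        nbhd[v] = set(reach) - {v}
    n = len(nodes)
    t = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            r = 1 if b in nbhd[a] else 0
            shared = len(nbhd[a] & nbhd[b])
            denom = min(len(nbhd[a]), len(nbhd[b])) + 1 - r
            val = (shared + r) / denom if denom > 0 else 0.0
            t[i, j] = t[j, i] = val
    return t


def gsva_walk_oracle(expr_df, gene_sets, tau=1.0, bandwidth_factor=0.25):
    """Module scores by plain per-sample loops: kernel CDF, ranks, walk."""
    genes = list(expr_df.index)
    samples = list(expr_df.columns)
    x = expr_df.to_numpy(dtype=float)
    p, n = x.shape

    z = np.zeros((p, n))
    for i in range(p):
        s = float(np.std(x[i], ddof=1))
        h = s * bandwidth_factor
        for j in range(n):
            total = 0.0
            for k in range(n):
                total += 0.5 * (1.0 + math.erf((x[i, j] - x[i, k]) / (h * math.sqrt(2))))
            z[i, j] = total / n

    scores = {}
    for name, members in gene_sets.items():
        member_set = set(members)
        in_set = [g in member_set for g in genes]
        k = sum(in_set)
        out = []
        for j in range(n):
            order = sorted(range(p), key=lambda i: (-z[i, j], i))
            wsum = 0.0
            for rank, i in enumerate(order, start=1):
                if in_set[i]:
                    wsum += abs(p / 2.0 - rank) ** tau
            nu, cum_in, cum_out = [], 0.0, 0
            for rank, i in enumerate(order, start=1):
                if in_set[i]:
                    cum_in += abs(p / 2.0 - rank) ** tau
                else:
                    cum_out += 1
                nu.append(cum_in / wsum - cum_out / (p - k))
            out.append(max(nu) + min(nu))
        scores[name] = out
    return scores, samples


def efron_log_partial_likelihood(beta, times, events, covariate):
    """Efron-tie log partial likelihood for a single covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    eta = beta * x
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        d = int(dead.sum())
        ll += eta[dead].sum()
        risk_sum = theta[at_risk].sum()
        tie_sum = theta[dead].sum()
        for ell in range(d):
            ll -= math.log(risk_sum - (ell / d) * tie_sum)
    return ll


def cox_grid_oracle(times, events, covariate, lo=-8.0, hi=8.0):
    """Maximize the Efron partial likelihood by nested grid search."""
    grid = np.linspace(lo, hi, 401)
    for _ in range(6):
        vals = [
            efron_log_partial_likelihood(b, times, events, covariate) for b in grid
        ]
        best = grid[int(np.argmax(vals))]
        width = (grid[-1] - grid[0]) / 10
        grid = np.linspace(best - width, best + width, 201)
    return float(best)
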