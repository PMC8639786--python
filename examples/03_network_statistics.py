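"""Distinctiveness, node strength, and consensus modularity of band networks.

Constructs four band-specific connectivity matrices with a shared planted
3-module structure plus band-specific noise, then (1) quantifies how
independent the band networks are via distinctiveness D = 1 - R^2, (2)
collapses one matrix onto per-node strengths with a permutation-null
significance mask, and (3) recovers the planted modules by consensus
clustering across bands.
"""

import numpy as np

from rhythmnet import consensus_modularity, distinctiveness, node_strength, strength_significance

rng = np.random.default_rng(0)
n = 30
labels = np.repeat([0, 1, 2], 10)
base = np.where(labels[:, None] == labels[None, :], 0.6, 0.1)

bands = {}
for name in ("theta", "beta", "high_beta", "gamma"):
    W = base * np.exp(0.3 * rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    bands[name] = W

d_raw = distinctiveness(bands["beta"], bands["gamma"]).d
d_self = distinctiveness(bands["beta"], bands["beta"]).d
print(f"distinctiveness D = 1 - R^2 (0 = identical spatial pattern, 1 = independent):")
print(f"  beta vs beta   D = {d_self:.2f}")
print(f"  beta vs gamma  D = {d_raw:.2f}  (same modules, independent noise)")

sm = strength_significance(bands["gamma"], n_perm=500, fdr_q=0.2, seed=1)
print(f"\ngamma node strengths: mean {sm.strength.mean():.3f}; "
      f"{int(sm.significance.sum())}/{n} sites exceed the equal-weight "
      "random-graph null (BH-FDR corrected)")

res = consensus_modularity(bands, n_reps=10, consensus_tau=0.25, seed=2)
print(f"\nconsensus modularity across the four bands:")
print(f"  modules found: {len(np.unique(res.partition))} (planted: 3)")
print(f"  modularity index q at resolution 1: {res.q:.3f}")
match = all(len(np.unique(labels[res.partition == k])) == 1
            for k in np.unique(res.partition))
print(f"  consensus partition matches the planted modules: {match}")
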