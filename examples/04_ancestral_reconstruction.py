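"""Ancestral trait reconstruction under Brownian motion, with truth known.

Simulates a growth-temperature-like trait on a 32-tip tree from a known
root state, reconstructs all internal node states by maximum likelihood,
and reports how well the truth is recovered (including whether the 95%
confidence intervals behave as advertised).
"""

from revecol import anc_ml, gen_tree, recovery_metrics, simulate_bm

tree = gen_tree(32, "random-split", seed=11)
root_truth = 66.0  # e.g. degrees C for an OGT-like trait
tips, true_nodes = simulate_bm(tree, sigma2=25.0, root_state=root_truth,
                               seed=12)

est = anc_ml(tree, tips)
rmse, bias, coverage = recovery_metrics(true_nodes, est)

root = tree.root.label
lo, hi = est.ci95[root]
print(f"tree: {tree.n_tips()} tips, {len(est.states)} internal nodes")
print(f"true root state      = {root_truth:.2f}")
print(f"ML root estimate     = {est.states[root]:.2f}  (95% CI {lo:.2f} .. {hi:.2f})")
print(f"rate estimate sigma2 = {est.sigma2_hat:.2f}  (true 25.0)")
print(f"node RMSE = {rmse:.2f}, bias = {bias:+.2f}, CI coverage = {coverage:.2f}")
print()
print("The ML state at each node is the inverse-path-length weighted blend")
print("of information from every adjacent subtree; with the true model the")
print("95% intervals should cover the truth for ~95% of nodes.")
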