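"""Shared helper: random trees with strictly positive branch lengths, whose
leaf-to-leaf path metric is additive by construction."""

from photocoord.phylo import TreeNode


def random_additive_tree(n_taxa, rng):
    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 2.0)))
        for i in range(n_taxa)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.5, 2.0))
        )
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)
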