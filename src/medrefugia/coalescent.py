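"""Standard n-coalescent genealogies and infinite-sites mutations.

This is the stochastic core shared by the synthetic-data generator and the
neutrality-test null distribution: exchangeable Kingman genealogies (the
interval with k active lineages is Exponential with rate k(k-1)/2, time in
units of 2N generations) and infinite-sites mutations placed on branches
either as a Poisson process (rate theta/2 per unit branch length) or
conditioned on an exact segregating-site count S (multinomial on branch
lengths, the classic fixed-S null simulator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Genealogy", "simulate_genealogy_arrays", "place_mutations",
           "mutation_stats"]


@dataclass
class Genealogy:
    """A binary coalescent tree over tips 0..n-1 in array form.

    Nodes 0..n-1 are tips (age 0); nodes n..2n-2 are internal, created in
    coalescence order so node 2n-2 is the root. ``parent[i]`` is -1 for the
    root. ``age[i]`` is the node's time before present.
    """

    n: int
    parent: np.ndarray
    age: np.ndarray

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        lens = np.zeros(2 * self.n - 1)
        for i in range(2 * self.n - 2):
            lens[i] = self.age[self.parent[i]] - self.age[i]
        return lens

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tips_below(self) -> list[np.ndarray]:
        """For each node, the sorted tip ids in its subtree."""
        below: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for t in range(self.n):
            below[t] = [t]
        # children lists; internal nodes are created bottom-up so a simple
        # pass in node order accumulates correctly
        children: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for i in range(2 * self.n - 2):
            children[self.parent[i]].append(i)
        for node in range(self.n, 2 * self.n - 1):
            acc: list[int] = []
            for c in children[node]:
                acc.extend(below[c])
            below[node] = sorted(acc)
        return [np.asarray(b, dtype=int) for b in below]

    def newick(self, labels: list[str] | None = None, digits: int = 10) -> str:
        if labels is None:
            labels = [f"t{i}" for i in range(self.n)]
        children: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for i in range(2 * self.n - 2):
            children[self.parent[i]].append(i)

        def fmt(node: int) -> str:
            if node < self.n:
                name = labels[node]
            else:
                kids = ",".join(fmt(c) for c in children[node])
                name = f"({kids})"
            if node == self.root:
                return name
            blen = self.age[self.parent[node]] - self.age[node]
            return f"{name}:{blen:.{digits}f}"

        return fmt(self.root) + ";"


def simulate_genealogy_arrays(n: int, rng: np.random.Generator) -> Genealogy:
    """Simulate one Kingman coalescent genealogy for ``n`` tips."""
    if n < 2:
        raise ValueError("coalescent genealogy requires n >= 2 samples")
    parent = np.full(2 * n - 1, -1, dtype=int)
    age = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = next_node
        parent[b] = next_node
        age[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return Genealogy(n=n, parent=parent, age=age)


def place_mutations(gen: Genealogy, rng: np.random.Generator,
                    theta: float | None = None,
                    s_fixed: int | None = None) -> np.ndarray:
    """Assign mutations to branches; returns the branch node id per mutation.

    Exactly one of ``theta`` (Poisson, rate theta/2 per unit length) or
    ``s_fixed`` (multinomial proportional to branch length) must be given.
    """
    if (theta is None) == (s_fixed is None):
        raise ValueError("specify exactly one of theta or s_fixed")
    lens = gen.branch_lengths()[: 2 * gen.n - 2]
    total = lens.sum()
    if theta is not None:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        n_mut = rng.poisson(theta / 2.0 * total)
    else:
        if s_fixed < 0:
            raise ValueError("s_fixed must be >= 0")
        n_mut = int(s_fixed)
    if n_mut == 0:
        return np.empty(0, dtype=int)
    probs = lens / total
    counts = rng.multinomial(n_mut, probs)
    return np.repeat(np.arange(2 * gen.n - 2), counts)


def mutation_stats(gen: Genealogy, mut_nodes: np.ndarray) -> dict:
    """Summary statistics implied by mutations on a genealogy.

    Returns segregating sites S, haplotype count H, mean pairwise
    differences kbar, and folded singleton counts U per tip (a mutation is a
    singleton when its minority side is one tip; the count is attributed to
    that tip, matching what one computes from an alignment without an
    outgroup).
    """
    n = gen.n
    below = gen.tips_below()
    carrier = np.zeros((len(mut_nodes), n), dtype=bool)
    for m, node in enumerate(mut_nodes):
        carrier[m, below[node]] = True
    c = carrier.sum(axis=1)
    # mean pairwise differences: each mutation separates c*(n-c) pairs
    kbar = float((2.0 * c * (n - c)).sum() / (n * (n - 1))) if len(c) else 0.0
    U = np.zeros(n)
    minority_one = c == 1
    U += carrier[minority_one].sum(axis=0)
    minority_other = c == n - 1
    U += (~carrier[minority_other]).sum(axis=0)
    # haplotypes: equivalence classes of carried-mutation patterns
    if len(mut_nodes):
        H = len({tuple(col) for col in carrier.T})
    else:
        H = 1
    return {"S": int(len(mut_nodes)), "H": H, "kbar": kbar, "U": U}
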