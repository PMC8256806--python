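"""Pure-drift genotype simulator on a population tree.

Allele frequencies start from an ancestral draw and diffuse root-to-leaf with
a Beta (Balding-Nichols) transition per branch: the child frequency has mean
``p0`` and variance ``c * p0 * (1 - p0)`` for branch drift coefficient ``c``.
Optional selected loci experience inflated drift (or a deterministic shift
toward fixation) on a chosen branch.  Genotypes are Binomial(2, p) draws under
Hardy-Weinberg within each leaf population.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import skbio

from driftscan.genotype_io import GenotypeDataset, SNPRecord


@dataclass
class _Node:
    name: str
    drift: float | None  # branch coefficient to parent; None at the root
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PopulationTree:
    """Rooted tree over populations; branch lengths are drift coefficients in (0, 1)."""

    def __init__(self, root: _Node, outgroup: str | None = None):
        self.root = root
        self.outgroup = outgroup
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self._walk(self.root):
            if node.name in seen:
                raise ValueError(f"duplicate node name {node.name!r}")
            seen.add(node.name)
            if node is not self.root:
                if node.drift is None or not 0.0 < node.drift < 1.0:
                    raise ValueError(
                        f"branch drift for {node.name!r} must lie in (0, 1), got {node.drift}"
                    )
        if not self.leaves():
            raise ValueError("tree has no leaves")
        if self.outgroup is not None and self.outgroup not in self.leaves():
            raise ValueError(f"outgroup {self.outgroup!r} is not a leaf")

    @staticmethod
    def _walk(node: _Node):
        yield node
        for ch in node.children:
            yield from PopulationTree._walk(ch)

    def leaves(self) -> list[str]:
        return [n.name for n in self._walk(self.root) if n.is_leaf]

    def branch_names(self) -> list[str]:
        return [n.name for n in self._walk(self.root) if n is not self.root]

    def node(self, name: str) -> _Node:
        for n in self._walk(self.root):
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "PopulationTree":
        """Parse a Newick string whose branch lengths are drift coefficients."""
        sk = skbio.TreeNode.read(io.StringIO(newick), convert_underscores=False)
        counter = [0]

        def convert(t) -> _Node:
            if t.name:
                name = str(t.name)
            else:
                counter[0] += 1
                name = f"anc{counter[0]}"
            drift = None if t.length is None else float(t.length)
            node = _Node(name=name, drift=drift)
            node.children = [convert(c) for c in t.children]
            return node

        root = convert(sk)
        root.drift = None
        return cls(root, outgroup=outgroup)

    def _node_paths(self) -> dict[str, list[_Node]]:
        """Root-to-leaf node lists (excluding the root) keyed by leaf name."""
        out: dict[str, list[_Node]] = {}

        def rec(node: _Node, acc: list[_Node]) -> None:
            nxt = acc if node is self.root else acc + [node]
            if node.is_leaf:
                out[node.name] = nxt
            for ch in node.children:
                rec(ch, nxt)

        rec(self.root, [])
        return out

    def kinship_matrix(self, exclude: Sequence[str] = ()) -> tuple[list[str], np.ndarray]:
        """Exact between-population covariance scaling implied by the tree.

        Under the Beta drift kernel, Var(p_leaf) = F_ii * p0(1-p0) with
        F_ii = 1 - prod(1 - c_k) along the path from the most recent common
        ancestor of the retained leaves down to the leaf, and
        Cov(p_i, p_j) = F_ij * p0(1-p0) with the product over the branches
        the two paths share below that ancestor.  Conditioning on the MRCA
        matches how the ancestral frequency is re-estimated per SNP when the
        matrix is used for the kinship-corrected differentiation test.
        """
        leaves = [l for l in self.leaves() if l not in set(exclude)]
        if not leaves:
            raise ValueError("no leaves left after exclusion")
        paths = self._node_paths()
        # depth of the MRCA = longest common prefix across all retained leaf paths
        mrca_depth = 0
        first = paths[leaves[0]]
        while all(
            mrca_depth < len(paths[l]) and paths[l][mrca_depth] is first[mrca_depth]
            for l in leaves
        ) and mrca_depth < len(first):
            mrca_depth += 1
        k = len(leaves)
        F = np.zeros((k, k))
        for a in range(k):
            for b in range(a, k):
                pa = paths[leaves[a]][mrca_depth:]
                pb = paths[leaves[b]][mrca_depth:]
                shared = [x.drift for x, y in zip(pa, pb) if x is y]
                F[a, b] = F[b, a] = (
                    1.0 - float(np.prod(1.0 - np.asarray(shared))) if shared else 0.0
                )
        return leaves, F


@dataclass
class SelectionSpec:
    """Loci under directional selection on one branch.

    ``mechanism`` is either ``"drift"`` (replace the branch coefficient with
    ``c_sel``, i.e. excess differentiation) or ``"shift"`` (deterministically
    move the frequency toward allele2 fixation by ``shift_frac`` of the gap).
    """

    branch: str
    snp_indices: Sequence[int]
    c_sel: float = 0.5
    mechanism: str = "drift"
    shift_frac: float = 0.8


@dataclass
class SimTruth:
    """Ground truth recorded by :func:`simulate_dataset`."""

    ancestral_freqs: np.ndarray
    leaf_freqs: dict[str, np.ndarray]
    selected_loci: list[tuple[int, str, str]]
    seed: int

    def to_tsv(self, path: str | Path, snps: list[SNPRecord]) -> None:
        pops = list(self.leaf_freqs)
        sel = {i: (b, m) for i, b, m in self.selected_loci}
        with open(path, "w") as fh:
            fh.write("snp_id\tancestral_freq\t" + "\t".join(f"freq_{p}" for p in pops))
            fh.write("\tselected\tbranch\tmechanism\n")
            for j, s in enumerate(snps):
                row = [s.snp_id, f"{self.ancestral_freqs[j]:.6f}"]
                row += [f"{self.leaf_freqs[p][j]:.6f}" for p in pops]
                if j in sel:
                    row += ["1", sel[j][0], sel[j][1]]
                else:
                    row += ["0", ".", "."]
                fh.write("\t".join(row) + "\n")


def drift_transition(
    p0: float | np.ndarray, c: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p0(1-c)/c, (1-p0)(1-c)/c) draws.

    Boundaries are absorbing: entries with p0 in {0, 1} are returned unchanged.
    """
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    c = np.broadcast_to(np.asarray(c, dtype=float), p0.shape)
    if ((c <= 0.0) | (c >= 1.0)).any():
        raise ValueError("drift coefficient c must lie in (0, 1)")
    if ((p0 < 0.0) | (p0 > 1.0)).any():
        raise ValueError("p0 must lie in [0, 1]")
    out = p0.copy()
    interior = (p0 > 0.0) & (p0 < 1.0)
    if interior.any():
        scale = (1.0 - c[interior]) / c[interior]
        a = p0[interior] * scale
        b = (1.0 - p0[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def study_shaped_tree(
    background_c: float = 0.02,
    landrace_c: float = 0.08,
    outgroup_c: float = 0.15,
) -> PopulationTree:
    """Desk-scale twin of the study design: outgroup D, then L, LW_Old, four farms."""
    c = background_c
    newick = (
        f"(((((LW_1:{c},LW_2:{c}):{c},(LW_3:{c},LW_4:{c}):{c}):{c},"
        f"LW_Old:{2 * c}):{c},L:{landrace_c}):{c},D:{outgroup_c});"
    )
    return PopulationTree.from_newick(newick, outgroup="D")


def simulate_dataset(
    tree: PopulationTree,
    n_snps: int,
    samples_per_pop: int | dict[str, int],
    ancestral_freq_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    selected_spec: Sequence[SelectionSpec] = (),
    seed: int = 0,
    n_chroms: int = 10,
    snp_spacing_bp: int = 25_000,
) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a genotype dataset by drifting frequencies down ``tree``.

    SNPs are laid out on ``n_chroms`` chromosomes at ``snp_spacing_bp``
    intervals in index order, so clustered ``snp_indices`` in a
    :class:`SelectionSpec` produce a contiguous genomic region.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    branch_names = set(tree.branch_names())
    for spec in selected_spec:
        if spec.branch not in branch_names:
            raise ValueError(f"selection branch {spec.branch!r} not in tree")
        idx = np.asarray(spec.snp_indices)
        if idx.size and (idx.min() < 0 or idx.max() >= n_snps):
            raise ValueError("selected snp_indices outside SNP range")

    rng = np.random.default_rng(seed)
    if ancestral_freq_dist is None:
        anc = rng.uniform(0.05, 0.95, size=n_snps)
    else:
        anc = np.asarray(ancestral_freq_dist(rng, n_snps), dtype=float)

    sel_by_branch: dict[str, list[SelectionSpec]] = {}
    for spec in selected_spec:
        sel_by_branch.setdefault(spec.branch, []).append(spec)

    leaf_freqs: dict[str, np.ndarray] = {}

    def descend(node: _Node, p: np.ndarray) -> None:
        for child in node.children:
            c_vec = np.full(n_snps, child.drift)
            shift_idx: list[tuple[np.ndarray, float]] = []
            for spec in sel_by_branch.get(child.name, []):
                idx = np.asarray(spec.snp_indices, dtype=int)
                if spec.mechanism == "drift":
                    c_vec[idx] = spec.c_sel
                elif spec.mechanism == "shift":
                    shift_idx.append((idx, spec.shift_frac))
                else:
                    raise ValueError(f"unknown selection mechanism {spec.mechanism!r}")
            p_child = drift_transition(p, c_vec, rng)
            for idx, frac in shift_idx:
                p_child[idx] = p_child[idx] + frac * (1.0 - p_child[idx])
            if child.is_leaf:
                leaf_freqs[child.name] = p_child
            else:
                descend(child, p_child)

    descend(tree.root, anc)

    counts = (
        {leaf: samples_per_pop for leaf in tree.leaves()}
        if isinstance(samples_per_pop, int)
        else dict(samples_per_pop)
    )
    for leaf in tree.leaves():
        if counts.get(leaf, 0) < 1:
            raise ValueError(f"samples_per_pop must be >= 1 for leaf {leaf!r}")

    snps = _snp_map(n_snps, n_chroms, snp_spacing_bp)
    sample_ids: list[str] = []
    populations: list[str] = []
    blocks = []
    for leaf in tree.leaves():
        k = counts[leaf]
        sample_ids += [f"{leaf}_{i + 1}" for i in range(k)]
        populations += [leaf] * k
        blocks.append(rng.binomial(2, leaf_freqs[leaf], size=(k, n_snps)).astype(np.int8))
    dosages = np.vstack(blocks)

    dataset = GenotypeDataset(sample_ids, populations, snps, dosages)
    truth = SimTruth(
        ancestral_freqs=anc,
        leaf_freqs=leaf_freqs,
        selected_loci=[
            (int(i), spec.branch, spec.mechanism)
            for spec in selected_spec
            for i in spec.snp_indices
        ],
        seed=seed,
    )
    return dataset, truth


def _snp_map(n_snps: int, n_chroms: int, spacing: int) -> list[SNPRecord]:
    per_chrom = -(-n_snps // n_chroms)  # ceil
    snps = []
    for j in range(n_snps):
        chrom = j // per_chrom + 1
        pos = (j % per_chrom) * spacing + 1
        snps.append(
            SNPRecord(snp_id=f"snp{j + 1}", chrom=str(chrom), pos_bp=pos, allele1="A", allele2="B")
        )
    return snps
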