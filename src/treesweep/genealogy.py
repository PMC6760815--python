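"""Labeled local genealogies and their reduction to lineage-count series.

A labeled genealogy is a rooted tree with branch lengths in generations and a
derived/ancestral allele assigned to every leaf.  Under the infinite-sites
assumption the derived leaves must form a clade.  The likelihood only sees the
tree through the counts of surviving lineages per allelic class at the grid
times: the derived process, the ancestral process, and the mixed process that
takes over once (going backward) the mutation has occurred and the lone
derived root lineage coalesces freely with the ancestral survivors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import TimeGrid

__all__ = [
    "LabeledGenealogy",
    "CountSeries",
    "InfiniteSitesViolation",
    "read_labeled_newick",
    "read_label_table",
    "read_tree_file",
    "extract_counts",
]

DERIVED = "derived"
ANCESTRAL = "ancestral"


class InfiniteSitesViolation(ValueError):
    """Derived leaves are not monophyletic: more than one mutation required."""


@dataclass
class LabeledGenealogy:
    """Rooted genealogy with node ages (generations) and leaf allele labels."""

    tree: dendropy.Tree
    labels: dict

    def __post_init__(self):
        self._annotate_ages()
        self._validate()

    def _annotate_ages(self):
        tree = self.tree
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                nd.depth = 0.0
            else:
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                if bl < 0:
                    raise ValueError(f"negative branch length {bl} in genealogy")
                nd.depth = nd.parent_node.depth + bl
        height = max(nd.depth for nd in tree.leaf_node_iter())
        # sums of float branch lengths leave ~1e-12 jitter on contemporaneous
        # leaves; snap near-zero ages so present-day samples count at t = 0
        tol = 1e-6 * max(height, 1.0)
        for nd in tree.preorder_node_iter():
            age = height - nd.depth
            nd.age = 0.0 if abs(age) < tol else age

    def _validate(self):
        leaves = list(self.tree.leaf_node_iter())
        if len(leaves) < 2:
            raise ValueError("genealogy needs at least two leaves")
        names = [lf.taxon.label for lf in leaves]
        missing = [n for n in names if n not in self.labels]
        if missing:
            raise ValueError(f"leaves missing from the label table: {missing}")
        bad = {n: a for n, a in self.labels.items()
               if n in names and a not in (DERIVED, ANCESTRAL)}
        if bad:
            raise ValueError(f"allele labels must be derived/ancestral, got {bad}")
        der = [lf for lf in leaves if self.labels[lf.taxon.label] == DERIVED]
        anc = [lf for lf in leaves if self.labels[lf.taxon.label] == ANCESTRAL]
        if not der or not anc:
            raise ValueError("need at least one derived and one ancestral leaf")
        # classify every node by the alleles beneath it
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                nd.n_der = int(self.labels[nd.taxon.label] == DERIVED)
                nd.n_anc = 1 - nd.n_der
            else:
                nd.n_der = sum(ch.n_der for ch in nd.child_nodes())
                nd.n_anc = sum(ch.n_anc for ch in nd.child_nodes())
        # derived MRCA: the youngest node subtending every derived leaf
        n_der_total = len(der)
        mrca = min(
            (nd for nd in self.tree.preorder_node_iter() if nd.n_der == n_der_total),
            key=lambda nd: nd.age,
        )
        if mrca.n_anc > 0:
            offenders = sorted(
                lf.taxon.label
                for lf in mrca.leaf_iter()
                if self.labels[lf.taxon.label] == ANCESTRAL
            )
            raise InfiniteSitesViolation(
                "infinite-sites violation: derived leaves are not monophyletic "
                f"(ancestral leaves {offenders} fall inside the derived clade)"
            )
        self._derived_mrca = mrca

    @property
    def n_der(self) -> int:
        return self.tree.seed_node.n_der

    @property
    def n_anc(self) -> int:
        return self.tree.seed_node.n_anc

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    @property
    def derived_mrca_age(self) -> float:
        return self._derived_mrca.age

    @property
    def derived_merge_age(self) -> float:
        """Age at which the derived-root lineage coalesces into the ancestral side."""
        parent = self._derived_mrca.parent_node
        return parent.age if parent is not None else self._derived_mrca.age

    def leaf_ages(self) -> dict:
        return {lf.taxon.label: lf.age for lf in self.tree.leaf_node_iter()}

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_label_table(source) -> dict:
    """Parse a two-column TSV ``leaf_id<TAB>allele`` into a label dict."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source).read()
    labels = {}
    for lineno, line in enumerate(text.strip().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"label table line {lineno}: expected two tab-separated fields")
        name, allele = parts[0].strip(), parts[1].strip().lower()
        if allele not in (DERIVED, ANCESTRAL):
            raise ValueError(f"label table line {lineno}: allele must be derived/ancestral")
        labels[name] = allele
    return labels


def read_labeled_newick(newick_text: str, labels: dict) -> LabeledGenealogy:
    """Parse one Newick tree (branch lengths in generations) with allele labels."""
    tree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return LabeledGenealogy(tree, labels)


def read_tree_file(path: str, labels: dict, thin: int = 1):
    """Yield genealogies from a file with one Newick string per line."""
    with open(path) as fh:
        kept = 0
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if i % max(1, thin) != 0:
                continue
            yield read_labeled_newick(line, labels)
            kept += 1


@dataclass
class CountSeries:
    """Lineage counts of the derived, ancestral, and mixed processes at grid times.

    ``c_der[i]`` etc. refer to time ``t_i``; entries older than the mutation
    (derived/ancestral) or younger than the derived-root coalescence (mixed)
    are bookkeeping values in the style of the companion table and do not all
    enter the likelihood.  ``entrants_*[i]`` count ancient leaves of each class
    entering during epoch i (zero for contemporaneous samples).
    """

    grid: TimeGrid
    c_der: np.ndarray
    c_anc: np.ndarray
    c_mix: np.ndarray
    n_der: int
    n_anc: int
    derived_mrca_age: float = 0.0
    entrants_der: np.ndarray | None = None
    entrants_anc: np.ndarray | None = None

    def __post_init__(self):
        self.c_der = np.asarray(self.c_der, dtype=int)
        self.c_anc = np.asarray(self.c_anc, dtype=int)
        self.c_mix = np.asarray(self.c_mix, dtype=int)
        n = self.grid.K + 1
        for name in ("c_der", "c_anc", "c_mix"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} needs one entry per grid time ({n})")
        if self.entrants_der is None:
            self.entrants_der = np.zeros(self.grid.K, dtype=int)
        if self.entrants_anc is None:
            self.entrants_anc = np.zeros(self.grid.K, dtype=int)
        self.entrants_der = np.asarray(self.entrants_der, dtype=int)
        self.entrants_anc = np.asarray(self.entrants_anc, dtype=int)

    def to_tsv(self, fh) -> None:
        fh.write("time_gen\tc_der\tc_anc\tc_mix\n")
        for t, d, a, m in zip(self.grid.times, self.c_der, self.c_anc, self.c_mix):
            fh.write(f"{t:.10g}\t{d}\t{a}\t{m}\n")

    @classmethod
    def from_tsv(cls, source, n_der: int | None = None, n_anc: int | None = None):
        text = source.read() if hasattr(source, "read") else open(source).read()
        rows = [ln.split("\t") for ln in text.strip().splitlines()]
        if rows and rows[0][0].startswith("time"):
            rows = rows[1:]
        t = [float(r[0]) for r in rows]
        d = [int(r[1]) for r in rows]
        a = [int(r[2]) for r in rows]
        m = [int(r[3]) for r in rows]
        grid = TimeGrid(tuple(t))
        return cls(grid, d, a, m,
                   n_der=n_der if n_der is not None else d[0],
                   n_anc=n_anc if n_anc is not None else a[0])


def extract_counts(gen: LabeledGenealogy, grid: TimeGrid) -> CountSeries:
    """Reduce a labeled genealogy to the three lineage-count processes.

    A branch is counted at time t iff ``child_age <= t < parent_age`` (a
    coalescence at exactly t has already happened by t); the root's stem is
    treated as extending to infinity so exactly one lineage survives above the
    root.  Counting convention for the three processes:

    * derived: branches whose descendants are all derived; held at 1 from the
      derived MRCA onward (the clade's root lineage, extended as bookkeeping
      after it coalesces);
    * ancestral: branches with only ancestral descendants while the derived
      root lineage is distinct; equal to the mixed count after it coalesces;
    * mixed: ancestral count plus the derived root lineage (extended to the
      present) until that lineage coalesces, then the total surviving count.
    """
    if gen.root_age > grid.horizon:
        raise ValueError(
            f"tree root at {gen.root_age:g} generations exceeds the grid horizon "
            f"{grid.horizon:g}; use a larger horizon"
        )
    times = grid.times
    merge_age = gen.derived_merge_age

    branches = []  # (child_age, parent_age, kind)
    for nd in gen.tree.preorder_node_iter():
        if nd.parent_node is None:
            parent_age = np.inf
        else:
            parent_age = nd.parent_node.age
        if nd.n_der and nd.n_anc:
            kind = "mix"
        elif nd.n_der:
            kind = "der"
        else:
            kind = "anc"
        branches.append((nd.age, parent_age, kind))

    n_t = times.size
    D = np.zeros(n_t, dtype=int)
    A = np.zeros(n_t, dtype=int)
    M = np.zeros(n_t, dtype=int)
    for child_age, parent_age, kind in branches:
        mask = (times >= child_age) & (times < parent_age)
        if kind == "der":
            D[mask] += 1
        elif kind == "anc":
            A[mask] += 1
        else:
            M[mask] += 1

    total = D + A + M
    after = times >= merge_age
    c_der = np.where(D > 0, D, 1)
    c_anc = np.where(after, total, A)
    c_mix = np.where(after, total, A + 1)

    # ancient leaves enter the count at their own age
    entr_der = np.zeros(grid.K, dtype=int)
    entr_anc = np.zeros(grid.K, dtype=int)
    for lf in gen.tree.leaf_node_iter():
        if lf.age > 0:
            i = grid.epoch_of(lf.age)
            if gen.labels[lf.taxon.label] == DERIVED:
                entr_der[i] += 1
            else:
                entr_anc[i] += 1

    return CountSeries(
        grid,
        c_der,
        c_anc,
        c_mix,
        n_der=int(np.sum([gen.labels[lf.taxon.label] == DERIVED
                          for lf in gen.tree.leaf_node_iter() if lf.age == 0])),
        n_anc=int(np.sum([gen.labels[lf.taxon.label] == ANCESTRAL
                          for lf in gen.tree.leaf_node_iter() if lf.age == 0])),
        derived_mrca_age=gen.derived_mrca_age,
        entrants_der=entr_der,
        entrants_anc=entr_anc,
    )
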