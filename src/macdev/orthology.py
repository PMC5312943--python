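"""Orthogroup set logic: paralog-divergence classes, comparator-species
preprocessing, cross-species program intersection, phylo-profiles, recently
acquired genes, and duplication-epoch assignment from gene trees.

Orthogroups (as emitted by an all-vs-all clustering tool) are consumed as a
flat table mapping each orthogroup to per-species gene lists. The focal
species' development-specific calls partition orthogroups into paralog
divergence classes; comparator species (microarray time courses with their
own floors and control conditions) supply the cross-species intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .expression import SampleDesign, classify_preferential

logger = logging.getLogger(__name__)


@dataclass
class OrthogroupTable:
    """orthogroup ID -> {species -> [gene IDs]}."""

    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {}
        for og, by_species in self.groups.items():
            for sp, genes in by_species.items():
                pool = seen.setdefault(sp, set())
                dup = pool.intersection(genes)
                if dup or len(set(genes)) != len(genes):
                    raise ValueError(
                        f"gene(s) assigned to more than one orthogroup for {sp}: "
                        f"{sorted(dup) or genes}"
                    )
                pool.update(genes)

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for by_species in self.groups.values():
            for sp in by_species:
                if sp not in out:
                    out.append(sp)
        return out

    def members(self, og: str, species: str) -> list[str]:
        return self.groups.get(og, {}).get(species, [])

    def group_of(self, species: str) -> dict[str, str]:
        """gene ID -> orthogroup ID for one species."""
        return {
            g: og
            for og, by_species in self.groups.items()
            for g in by_species.get(species, [])
        }

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OrthogroupTable":
        """Build from a long table with columns orthogroup_id, species, gene_id."""
        groups: dict[str, dict[str, list[str]]] = {}
        for r in table.itertuples():
            groups.setdefault(str(r.orthogroup_id), {}).setdefault(
                str(r.species), []
            ).append(str(r.gene_id))
        return cls(groups)

    def to_table(self) -> pd.DataFrame:
        rows = [
            (og, sp, g)
            for og, by_species in self.groups.items()
            for sp, genes in by_species.items()
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["orthogroup_id", "species", "gene_id"])

    @classmethod
    def from_orthofinder_csv(cls, path) -> "OrthogroupTable":
        """Read the Orthogroups.csv dialect: one row per orthogroup, one
        tab-separated column per species holding a comma-separated gene list."""
        wide = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        groups: dict[str, dict[str, list[str]]] = {}
        for og, row in wide.iterrows():
            by_species = {}
            for sp, cell in row.items():
                if isinstance(cell, str) and cell.strip():
                    by_species[str(sp)] = [g.strip() for g in cell.split(",") if g.strip()]
            groups[str(og)] = by_species
        return cls(groups)


def _specific_set(calls) -> set[str]:
    """Accept a calls frame (``specific`` column), mapping, or plain iterable."""
    if isinstance(calls, pd.DataFrame):
        return set(calls.index[calls["specific"].astype(bool)])
    if isinstance(calls, pd.Series):
        return set(calls.index[calls.astype(bool)])
    if isinstance(calls, dict):
        return {g for g, flag in calls.items() if flag}
    return set(calls)


@dataclass
class ParalogClassification:
    """Per-orthogroup paralog divergence class and summary counts.

    Classes partition every orthogroup: ``all_specific`` / ``mixed`` / ``none``
    for groups with < max_members focal genes, ``excluded_oversize`` otherwise.
    """

    classes: dict[str, str]
    summary: dict[str, int] = field(default_factory=dict)

    def count(self, klass: str) -> int:
        return sum(1 for c in self.classes.values() if c == klass)


def classify_paralog_divergence(
    og: OrthogroupTable,
    calls,
    focal_species: str,
    max_members: int = 20,
    require_paralogs: bool = True,
) -> ParalogClassification:
    """Partition orthogroups by the development-specific status of focal members.

    ``all_specific``: every focal member specific; ``mixed``: at least one
    specific and one non-specific member; ``none``: no specific member (also
    groups without focal members); ``excluded_oversize``: >= ``max_members``
    focal members. Focal genes absent from the call set count as non-specific
    (they fell below the quality filter) and are tallied in the log.

    Summary counts restrict "considered" groups to those with >= 2 focal
    members when ``require_paralogs`` (paralogous gene sets) — the scale at
    which divergence of duplicates is assessed.
    """
    if focal_species not in og.species:
        raise ValueError(f"focal species {focal_species!r} absent from orthogroup table")
    specific = _specific_set(calls)
    called = (
        set(calls.index) if isinstance(calls, (pd.DataFrame, pd.Series))
        else set(calls) if isinstance(calls, dict) else specific
    )
    min_members = 2 if require_paralogs else 1
    classes: dict[str, str] = {}
    uncalled = 0
    considered = specific_containing = member_mrnas = mixed = all_spec = 0
    for og_id, by_species in og.groups.items():
        focal = by_species.get(focal_species, [])
        uncalled += sum(1 for g in focal if g not in called)
        if len(focal) >= max_members:
            classes[og_id] = "excluded_oversize"
            continue
        flags = [g in specific for g in focal]
        if focal and all(flags):
            classes[og_id] = "all_specific"
        elif any(flags):
            classes[og_id] = "mixed"
        else:
            classes[og_id] = "none"
        if len(focal) >= min_members:
            considered += 1
            if any(flags):
                specific_containing += 1
                member_mrnas += len(focal)
                if all(flags):
                    all_spec += 1
                else:
                    mixed += 1
    if uncalled:
        logger.info("%d focal genes without calls treated as non-specific", uncalled)
    summary = {
        "considered": considered,
        "specific_containing": specific_containing,
        "member_mrnas": member_mrnas,
        "mixed": mixed,
        "all_specific": all_spec,
        "oversize": sum(1 for c in classes.values() if c == "excluded_oversize"),
        "uncalled_focal_genes": uncalled,
    }
    return ParalogClassification(classes, summary)


@dataclass(frozen=True)
class PlatformSpec:
    """Comparator microarray preprocessing parameters.

    ``floor``: log2 intensity below which a gene (in all experiments) is
    dropped; ``probe_map``: probe ID -> gene ID (None when the matrix is
    already gene-centric); ``control_conditions``: conditions whose sample
    mean is subtracted and which specific mRNAs must exceed.
    """

    floor: float
    control_conditions: tuple[str, ...]
    probe_map: dict[str, str] | None = None


def preprocess_comparator(
    matrix: pd.DataFrame, platform: PlatformSpec, design: SampleDesign
) -> pd.DataFrame:
    """Comparator microarray preprocessing to a relative log2 matrix.

    Probes (if a probe map is given) are collapsed per gene by geometric
    mean on the intensity scale; intensities are log2-transformed; genes whose
    log2 value stays below the platform floor in every experiment are removed;
    values are normalized by subtracting the mean over control-condition
    samples.
    """
    if platform.probe_map is not None:
        unknown = [p for p in matrix.index if p not in platform.probe_map]
        if unknown:
            raise ValueError(f"unknown probe IDs: {unknown[:10]}" +
                             (" ..." if len(unknown) > 10 else ""))
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("probe intensities must be positive for geometric-mean collapse")
        gene_index = pd.Index([platform.probe_map[p] for p in matrix.index], name="gene_id")
        logged = np.log2(matrix.set_axis(gene_index))
        collapsed = logged.groupby(level=0).mean()  # geometric mean in log space
    else:
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive for log2 transform")
        collapsed = np.log2(matrix)
    keep = (collapsed >= platform.floor).any(axis=1)
    collapsed = collapsed.loc[keep]
    ctrl_samples = [
        s
        for cond in platform.control_conditions
        for s in design.condition_samples(cond)
        if s in collapsed.columns
    ]
    if not ctrl_samples:
        raise ValueError("no control-condition samples present for normalization")
    return collapsed.sub(collapsed[ctrl_samples].mean(axis=1), axis=0)


def classify_comparator(
    rel: pd.DataFrame,
    design: SampleDesign,
    dev_conditions: tuple[str, ...],
    control_conditions: tuple[str, ...],
    fold: float = 3.0,
) -> pd.DataFrame:
    """3-fold rule for a comparator species: a gene is specific when some
    developmental condition mean exceeds each control condition mean by
    >= log2(fold)."""
    return classify_preferential(
        rel, design, fold=fold,
        dev_conditions=dev_conditions, control_conditions=control_conditions,
    )


def union_inclusion_exclusion(a: int, b: int, both: int) -> int:
    """|A ∪ B| = |A| + |B| - |A ∩ B| for two comparator intersections."""
    return a + b - both


@dataclass
class IntersectionReport:
    """Per-orthogroup cross-species flags and aggregate intersection counts."""

    table: pd.DataFrame  # index og; focal_specific, <sp>_specific, <sp>_present
    counts: dict[str, int]


def intersect_programs(
    og: OrthogroupTable,
    focal_calls,
    comparator_calls: dict[str, object],
    focal_species: str,
    required_presence: list[str] | None = None,
) -> IntersectionReport:
    """Intersect the focal developmental program with comparator programs.

    An orthogroup intersects a comparator when >= 1 focal member is
    development-specific AND >= 1 member in that comparator species is
    specific under its own pipeline. ``required_presence`` restricts the
    universe to orthogroups with >= 1 member in each listed species. For two
    comparators the union obeys inclusion-exclusion (asserted).
    """
    if not comparator_calls:
        raise ValueError("need at least one comparator call set")
    schema = set(og.species)
    for sp in required_presence or []:
        if sp not in schema:
            raise ValueError(f"required species {sp!r} absent from orthogroup table")
    focal_specific = _specific_set(focal_calls)
    comp_specific = {sp: _specific_set(c) for sp, c in comparator_calls.items()}
    rows = []
    for og_id, by_species in og.groups.items():
        if required_presence and any(not by_species.get(sp) for sp in required_presence):
            continue
        row: dict[str, object] = {"orthogroup_id": og_id}
        row["focal_specific"] = any(
            g in focal_specific for g in by_species.get(focal_species, [])
        )
        for sp in og.species:
            row[f"{sp}_present"] = bool(by_species.get(sp))
        for sp, spec in comp_specific.items():
            row[f"{sp}_specific"] = any(g in spec for g in by_species.get(sp, []))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("orthogroup_id") if rows else pd.DataFrame()
    counts: dict[str, int] = {}
    if not table.empty:
        hit_sets = {
            sp: set(table.index[table["focal_specific"] & table[f"{sp}_specific"]])
            for sp in comp_specific
        }
        for sp, hits in hit_sets.items():
            counts[sp] = len(hits)
        union = set().union(*hit_sets.values())
        counts["union"] = len(union)
        if len(hit_sets) == 2:
            (a_sp, a), (b_sp, b) = hit_sets.items()
            counts["both"] = len(a & b)
            assert counts["union"] == union_inclusion_exclusion(
                counts[a_sp], counts[b_sp], counts["both"]
            )
    else:
        counts = {sp: 0 for sp in comp_specific} | {"union": 0}
    return IntersectionReport(table, counts)


def phylo_profile(og: OrthogroupTable, gene_set, focal_species: str):
    """Species x orthogroup presence over orthogroups containing ``gene_set``.

    Presence means the orthogroup has >= 1 member of that species. Returns
    (presence matrix, per-species counts).
    """
    gene_set = set(gene_set)
    group_of = og.group_of(focal_species)
    target_ogs = sorted({group_of[g] for g in gene_set if g in group_of})
    species = og.species
    presence = pd.DataFrame(
        [[bool(og.members(o, sp)) for o in target_ogs] for sp in species],
        index=species,
        columns=target_ogs,
    )
    return presence, presence.sum(axis=1)


def identify_recent_genes(
    og: OrthogroupTable,
    focal_calls,
    focal_species: str,
    sister_species: list[str],
    excluded_species: list[str],
) -> tuple[list[str], list[str]]:
    """Recently acquired development-specific genes.

    Returns focal genes that are development-specific, whose orthogroup has
    >= 1 member in some sister species and no member in any excluded species.
    Singletons (genes in no orthogroup) cannot qualify. Returns (genes,
    orthogroups).
    """
    if set(sister_species) & set(excluded_species):
        raise ValueError("sister and excluded species must be disjoint")
    specific = _specific_set(focal_calls)
    genes: list[str] = []
    ogs: set[str] = set()
    for og_id, by_species in og.groups.items():
        if not any(by_species.get(sp) for sp in sister_species):
            continue
        if any(by_species.get(sp) for sp in excluded_species):
            continue
        hits = [g for g in by_species.get(focal_species, []) if g in specific]
        if hits:
            genes.extend(hits)
            ogs.add(og_id)
    return sorted(genes), sorted(ogs)


@dataclass
class Epoch:
    """Duplication epoch on the species tree.

    ``status`` is "resolved" or "unresolved"; for resolved epochs the
    duplication is placed on the branch above the LCA of the species observed
    in the two paralog clades: after divergence from ``after`` (nearest
    outgroup species), before divergence of ``before`` (the clade under the
    LCA).
    """

    status: str
    after: tuple[str, ...] = ()
    before: tuple[str, ...] = ()

    def describe(self) -> str:
        if self.status != "resolved":
            return "unresolved"
        after = ", ".join(self.after) if self.after else "all sampled outgroups"
        before = ", ".join(self.before)
        return f"after divergence from {after}, before divergence of {before}"


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        tree.is_rooted = True
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick", rooting="force-rooted")


def duplication_epoch(
    gene_tree, species_tree, focal_paralogs: list[str], focal_species: str
) -> Epoch:
    """Place a duplication on the species tree from the paralogs' bifurcation.

    Gene-tree leaves are labelled ``species|gene``. The duplication node is
    the gene-tree MRCA of the focal paralogs; the epoch is the species-tree
    branch above the LCA of the union of species found in its two child
    clades. Unresolved when fewer than two paralogs are present in the tree
    or the bifurcation is a polytomy.
    """
    gtree = _load_tree(gene_tree)
    stree = _load_tree(species_tree)

    def leaf_info(leaf) -> tuple[str, str]:
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        sp, _, gene = label.partition("|")
        return sp.strip(), gene.strip()

    paralog_leaves = [
        lf for lf in gtree.leaf_node_iter()
        if leaf_info(lf)[0] == focal_species and leaf_info(lf)[1] in set(focal_paralogs)
    ]
    if len(paralog_leaves) < 2:
        return Epoch("unresolved")
    mrca = gtree.mrca(taxa=[lf.taxon for lf in paralog_leaves])
    children = mrca.child_nodes()
    if len(children) != 2:
        return Epoch("unresolved")
    paralog_set = {id(lf) for lf in paralog_leaves}
    clade_species: set[str] = set()
    for child in children:
        leaves = child.leaf_nodes()
        if not any(id(lf) in paralog_set for lf in leaves):
            return Epoch("unresolved")
        clade_species.update(leaf_info(lf)[0] for lf in leaves)

    s_taxa = {t.label: t for t in stree.taxon_namespace}
    observed = sorted(sp for sp in clade_species if sp in s_taxa)
    if not observed:
        return Epoch("unresolved")
    if len(observed) == 1:
        lca = stree.find_node_with_taxon_label(observed[0])
    else:
        lca = stree.mrca(taxa=[s_taxa[sp] for sp in observed])
    before = tuple(sorted(lf.taxon.label for lf in lca.leaf_nodes()))
    parent = lca.parent_node
    if parent is None:
        after: tuple[str, ...] = ()
    else:
        inside = set(before)
        after = tuple(
            sorted(
                lf.taxon.label for lf in parent.leaf_nodes()
                if lf.taxon.label not in inside
            )
        )
    return Epoch("resolved", after=after, before=before)


def read_newick(path) -> dendropy.Tree:
    """Load a rooted newick tree from a file path or handle."""
    if hasattr(path, "read"):
        return dendropy.Tree.get(file=path, schema="newick", rooting="force-rooted")
    return dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
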