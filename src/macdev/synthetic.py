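"""Synthetic inputs with planted structure for every pipeline stage.

The generators emulate the study conditions end-to-end without sequencing
data: a 14-sample conjugation time course (vegetative and 0/6/12/24/48/72 h
post-mixing, two replicates each) with temporally co-regulated planted
modules on a constitutive background; an orthogroup table with planted
paralog-divergence classes at the scale the analysis reports; promoter sets
with a position-biased planted motif at realistic foreground/background
occurrence rates; and a tissue compendium with a planted site-biased gene
set. Every generator returns ground-truth labels alongside the data and is
bitwise deterministic for a fixed seed.

Noise model: additive Gaussian noise on the log2(abundance+1) scale, clipped
at zero abundance after back-transforming — i.e. log-normal abundance noise
on the scale the downstream pipeline works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CONDITIONS, SampleDesign
from .motifs import IUPAC, Flank, FlankSet, validate_iupac

PARALOG_CLASSES = ("all_specific", "mixed", "none", "oversize")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for generated records.

    Only the fields relevant to the generator that produced the truth are
    populated; each generated record carries exactly one label.
    """

    gene_modules: dict[str, str] = field(default_factory=dict)
    orthogroup_classes: dict[str, str] = field(default_factory=dict)
    gene_specific: dict[str, bool] = field(default_factory=dict)
    promoter_plants: dict[str, tuple[bool, int | None]] = field(default_factory=dict)
    tissue_sites: dict[str, str | None] = field(default_factory=dict)


@dataclass
class ModuleSpec:
    """One planted temporal module: genes induced at a peak condition."""

    size: int
    peak_condition: str
    induction_fold: float = 8.0

    def __post_init__(self) -> None:
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")
        if self.peak_condition not in CONDITIONS:
            raise ValueError(f"unknown peak condition {self.peak_condition!r}")


@dataclass
class TimecourseSpec:
    """Parameters of the synthetic conjugation time course."""

    n_genes: int = 200
    design: SampleDesign = field(default_factory=SampleDesign.default_timecourse)
    module_specs: list[ModuleSpec] = field(default_factory=list)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        present = set(c for c, _ in self.design.samples.values())
        missing = set(CONDITIONS) - present
        if missing:
            raise ValueError(f"design lacks conditions: {sorted(missing)}")


def generate_timecourse(spec: TimecourseSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a gene x sample FPKM-like abundance matrix with planted modules.

    Planted-module genes have expected log2 abundance elevated by
    log2(induction_fold) at their peak condition relative to the 0 h /
    vegetative baseline; all other genes are constitutive. Deterministic for
    a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.design.sample_ids
    sample_conditions = [spec.design.samples[s][0] for s in samples]
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    baseline = np.clip(baseline, 0.5, None)
    bump = np.zeros((spec.n_genes, len(samples)))
    truth = SyntheticTruth()
    cursor = 0
    for m, mod in enumerate(spec.module_specs, start=1):
        rows = slice(cursor, cursor + mod.size)
        cols = [j for j, c in enumerate(sample_conditions) if c == mod.peak_condition]
        bump[rows, [c for c in cols]] = np.log2(mod.induction_fold)
        for g in genes[cursor:cursor + mod.size]:
            truth.gene_modules[g] = f"module_{m}"
        cursor += mod.size
    for g in genes[cursor:]:
        truth.gene_modules[g] = "constitutive"

    log_expr = (
        baseline[:, None]
        + bump
        + rng.normal(0.0, spec.noise_sd, (spec.n_genes, len(samples)))
    )
    abundance = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    return pd.DataFrame(abundance, index=genes, columns=samples), truth


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    keys = list(proportions)
    exact = np.array([proportions[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def generate_orthogroups(
    species: list[str],
    n_groups: int,
    class_mix: dict[str, float],
    seed: int = 0,
    focal_species: str | None = None,
) -> tuple["OrthogroupTable", SyntheticTruth]:
    """Simulate an orthogroup table with planted paralog-divergence classes.

    Class counts follow ``class_mix`` proportions deterministically (largest
    remainder; the first k groups get class c, in the canonical class order),
    so planted truth counts are exact. Oversize groups get >= 20 focal
    members. The truth also carries the implied focal development-specific
    flags.
    """
    from .orthology import OrthogroupTable

    if not species:
        raise ValueError("species list must be non-empty")
    unknown = set(class_mix) - set(PARALOG_CLASSES)
    if unknown:
        raise ValueError(f"unknown paralog classes: {sorted(unknown)}")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    focal = focal_species or species[0]
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n_groups, class_mix)

    truth = SyntheticTruth()
    groups: dict[str, dict[str, list[str]]] = {}
    gene_serial = 0

    def new_genes(n: int) -> list[str]:
        nonlocal gene_serial
        out = [f"{focal}_g{gene_serial + i:05d}" for i in range(n)]
        gene_serial += n
        return out

    og_serial = 0
    for klass in PARALOG_CLASSES:
        for _ in range(counts.get(klass, 0)):
            og_id = f"OG{og_serial:06d}"
            og_serial += 1
            if klass == "oversize":
                n_focal = int(rng.integers(20, 25))
                flags = rng.random(n_focal) < 0.5
            elif klass == "all_specific":
                n_focal = int(rng.integers(2, 5))
                flags = np.ones(n_focal, bool)
            elif klass == "mixed":
                n_focal = int(rng.integers(2, 5))
                flags = rng.random(n_focal) < 0.5
                flags[0], flags[-1] = True, False
            else:  # none
                n_focal = int(rng.integers(2, 4))
                flags = np.zeros(n_focal, bool)
            focal_genes = new_genes(n_focal)
            by_species: dict[str, list[str]] = {focal: focal_genes}
            for sp in species:
                if sp == focal:
                    continue
                if rng.random() < 0.7:
                    k = int(rng.integers(1, 4))
                    by_species[sp] = [f"{sp}_{og_id}_g{j}" for j in range(k)]
            groups[og_id] = by_species
            truth.orthogroup_classes[og_id] = klass
            for g, flag in zip(focal_genes, flags):
                truth.gene_specific[g] = bool(flag)
    return OrthogroupTable(groups), truth


def generate_promoters(
    n_fg: int,
    n_bg: int,
    motif: str,
    plant_rate_fg: float,
    plant_rate_bg: float,
    position_law: tuple = ("uniform",),
    position_law_bg: tuple = ("uniform",),
    gc: float = 0.3,
    seed: int = 0,
    length: int = 500,
    side: str = "upstream",
) -> tuple[FlankSet, FlankSet, SyntheticTruth]:
    """Simulate promoter (flank) sets with a planted motif.

    Each sequence is i.i.d. nucleotides at the given GC content; the motif
    (IUPAC; degenerate positions resolved randomly per plant) is inserted
    with the set's plant rate, at the distance given by the set's position
    law: ``("fixed", d)`` plants the motif start exactly d nt from the
    CDS-proximal end, ``("uniform",)`` uniformly over valid positions.
    ``position_law`` governs the foreground, ``position_law_bg`` the
    background (uniform by default, so a fixed foreground law creates the
    positional bias the K-S statistics detect).
    """
    motif = validate_iupac(motif)
    if not (0 <= plant_rate_fg <= 1 and 0 <= plant_rate_bg <= 1):
        raise ValueError("plant rates must lie in [0, 1]")
    if len(motif) > length:
        raise ValueError("motif longer than sequence length")
    for law in (position_law, position_law_bg):
        if law[0] == "fixed" and not (len(motif) <= law[1] <= length):
            raise ValueError("fixed plant distance incompatible with lengths")
        if law[0] not in ("fixed", "uniform"):
            raise ValueError(f"unknown position law {law[0]!r}")
    rng = np.random.default_rng(seed)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    def instantiate(rng) -> str:
        return "".join(rng.choice(list(IUPAC[c])) for c in motif)

    def make_set(prefix: str, n: int, rate: float, law: tuple) -> tuple[FlankSet, dict]:
        flanks: dict[str, Flank] = {}
        plants: dict[str, tuple[bool, int | None]] = {}
        for i in range(n):
            gene = f"{prefix}{i:05d}"
            seq = "".join(rng.choice(alphabet, size=length, p=base_p))
            planted = bool(rng.random() < rate)
            pos = None
            if planted:
                if law[0] == "fixed":
                    distance = int(law[1])
                else:
                    distance = int(rng.integers(len(motif), length + 1))
                start = length - distance if side == "upstream" else distance
                inst = instantiate(rng)
                seq = seq[:start] + inst + seq[start + len(motif):]
                pos = distance
            flanks[gene] = Flank(gene, seq, side)
            plants[gene] = (planted, pos)
        return FlankSet(flanks, side), plants

    fg, fg_truth = make_set("fg", n_fg, plant_rate_fg, position_law)
    bg, bg_truth = make_set("bg", n_bg, plant_rate_bg, position_law_bg)
    truth = SyntheticTruth(promoter_plants={**fg_truth, **bg_truth})
    return fg, bg, truth


def generate_tissue_matrix(
    n_genes: int,
    n_sites: int,
    biased_set_size: int,
    bias_fold: float,
    seed: int = 0,
    noise_sd: float = 0.1,
    samples_per_site: int = 2,
) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Simulate a gene x sample tissue compendium with a site-biased gene set.

    The first ``biased_set_size`` genes have one designated site elevated by
    log2(bias_fold) in expectation over all other sites. Returns the raw
    abundance matrix, the sample -> site map, and the truth (gene -> biased
    site, or None for unbiased genes).
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if biased_set_size > n_genes:
        raise ValueError("biased_set_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    sites = [f"site{j:02d}" for j in range(n_sites)]
    samples = [f"{s}_s{r}" for s in sites for r in range(1, samples_per_site + 1)]
    site_map = {f"{s}_s{r}": s for s in sites for r in range(1, samples_per_site + 1)}
    genes = [f"hgene{i:04d}" for i in range(n_genes)]

    baseline = np.clip(rng.normal(4.0, 1.0, n_genes), 0.5, None)
    target = rng.integers(0, n_sites, n_genes)
    log_expr = np.tile(baseline[:, None], (1, len(samples)))
    for i in range(biased_set_size):
        for j, s in enumerate(samples):
            if site_map[s] == sites[target[i]]:
                log_expr[i, j] += np.log2(bias_fold)
    log_expr += rng.normal(0.0, noise_sd, log_expr.shape)
    raw = pd.DataFrame(
        np.clip(np.exp2(log_expr) - 1.0, 0.0, None), index=genes, columns=samples
    )
    truth = SyntheticTruth(
        tissue_sites={
            g: (sites[target[i]] if i < biased_set_size else None)
            for i, g in enumerate(genes)
        }
    )
    return raw, site_map, truth
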