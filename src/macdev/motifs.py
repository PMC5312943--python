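"""CDS-flanking sequence extraction and linear motif statistics.

Flanks of up to 500 nt upstream (or downstream) of coding sequences are
extracted in coding-strand orientation, truncated at record ends, at
overlapping annotated CDSs and at terminal telomeric repeats, and dropped
below 80 nt. Enriched motifs are found by exhaustive k-mer testing (k = 8-12)
with ZOOPS counting (presence/absence per sequence, both strands collapsed to
a canonical k-mer) and an upper-tail hypergeometric score, followed by greedy
redundancy collapse. Downstream statistics: positional bias of motif
occurrences relative to the CDS-proximal flank end (two-sample
Kolmogorov-Smirnov) and conservation in ortholog flanks (upper-tail binomial
against a background occurrence rate).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import hypergeom_upper

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
TELOMERE_UNITS = ("CCCCAAAA", "GGGGTTTT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(motif: str) -> str:
    motif = motif.upper()
    bad = sorted(set(motif) - set(IUPAC))
    if bad:
        raise ValueError(f"non-IUPAC symbols in motif: {bad}")
    return motif


def iupac_pattern(motif: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in validate_iupac(motif)))


@dataclass(frozen=True)
class Flank:
    gene_id: str
    seq: str
    side: str  # upstream | downstream


@dataclass
class FlankSet:
    """Coding-strand flank sequences keyed by gene ID.

    Upstream flanks are stored 5'->3' with the CDS-proximal end on the
    *right*; downstream flanks have the proximal end on the left.
    """

    flanks: dict[str, Flank] = field(default_factory=dict)
    side: str = "upstream"

    def __len__(self) -> int:
        return len(self.flanks)

    def sequences(self) -> dict[str, str]:
        return {g: f.seq for g, f in self.flanks.items()}

    def proximal_distance(self, gene_id: str, match_start: int, match_len: int = 0) -> int:
        """Distance (nt) from a match start to the CDS-proximal flank end."""
        seq = self.flanks[gene_id].seq
        if self.side == "upstream":
            return len(seq) - match_start
        return match_start

    def to_fasta(self, handle) -> None:
        for g, f in self.flanks.items():
            handle.write(f">{g}\n{f.seq}\n")

    @classmethod
    def from_fasta(cls, handle, side: str = "upstream") -> "FlankSet":
        from Bio import SeqIO

        flanks = {
            rec.id: Flank(rec.id, str(rec.seq).upper(), side)
            for rec in SeqIO.parse(handle, "fasta")
        }
        return cls(flanks, side)


def _telomere_extent(seq: str, from_start: bool) -> int:
    """Length of the maximal terminal run of telomeric-repeat units."""
    best = 0
    for unit in TELOMERE_UNITS:
        n = 0
        u = len(unit)
        while True:
            if from_start:
                chunk = seq[n * u:(n + 1) * u]
            else:
                end = len(seq) - n * u
                chunk = seq[end - u:end] if end - u >= 0 else ""
            if chunk == unit:
                n += 1
            else:
                break
        best = max(best, n * u)
    return best


def extract_flanks(
    annotations: pd.DataFrame,
    genome: dict[str, str],
    length: int = 500,
    side: str = "upstream",
    min_len: int = 80,
    trim_telomeres: bool = True,
) -> FlankSet:
    """Extract CDS-flanking sequences in coding-strand orientation.

    ``annotations`` columns: record_id, start, end, strand, gene_id with
    0-based half-open coordinates on the forward strand. Flanks are truncated
    at record ends, at any overlapping annotated CDS, and at terminal
    telomeric repeats (C4A4 / G4T4 unit runs at record ends); flanks shorter
    than ``min_len`` are dropped.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    by_record: dict[str, list[tuple[int, int]]] = {}
    for r in annotations.itertuples():
        by_record.setdefault(str(r.record_id), []).append((int(r.start), int(r.end)))
    tel: dict[str, tuple[int, int]] = {}
    flanks: dict[str, Flank] = {}
    for r in annotations.itertuples():
        rec_id, start, end = str(r.record_id), int(r.start), int(r.end)
        strand, gene = str(r.strand), str(r.gene_id)
        if rec_id not in genome:
            raise ValueError(f"record {rec_id!r} (gene {gene}) absent from genome")
        record = genome[rec_id].upper()
        if not (0 <= start < end <= len(record)):
            raise ValueError(f"coordinates outside record for gene {gene}")
        if rec_id not in tel:
            if trim_telomeres:
                tel[rec_id] = (
                    _telomere_extent(record, True),
                    len(record) - _telomere_extent(record, False),
                )
            else:
                tel[rec_id] = (0, len(record))
        lo_bound, hi_bound = tel[rec_id]
        # genomic flank window, adjacent to the CDS on the appropriate side
        left_of_cds = (side == "upstream") == (strand == "+")
        if left_of_cds:
            lo, hi = max(start - length, 0), start
        else:
            lo, hi = end, min(end + length, len(record))
        lo, hi = max(lo, lo_bound), min(hi, hi_bound)
        # truncate at overlapping annotated CDSs, keeping the proximal portion
        for s2, e2 in by_record[rec_id]:
            if (s2, e2) == (start, end) or e2 <= lo or s2 >= hi:
                continue
            if left_of_cds:
                lo = max(lo, min(e2, hi))
            else:
                hi = min(hi, max(s2, lo))
        if hi - lo < min_len:
            continue
        seq = record[lo:hi]
        if strand == "-":
            seq = revcomp(seq)
        flanks[gene] = Flank(gene, seq, side)
    return FlankSet(flanks, side)


@dataclass
class MotifStats:
    """Occurrence and significance statistics for one motif."""

    motif: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p_enrichment: float
    median_fg: float | None = None
    median_bg: float | None = None
    ks_p: float | None = None
    conservation_k: int | None = None
    conservation_n: int | None = None
    conservation_p: float | None = None


def _canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (lexicographic min of k-mer / reverse complement) k-mers
    present in a sequence; k-mers containing N are skipped."""
    rc = revcomp(seq)
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        if "N" in fwd:
            continue
        rev = rc[n - i - k:n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def _min_detectable_count(n_fg: int, n_total: int, p_threshold: float) -> int:
    """Smallest foreground presence count that can reach the threshold even
    with zero background hits. Pruning below this count cannot change the
    reported motif set."""
    for x in range(1, n_fg + 1):
        if hypergeom_upper(x, x, n_fg, n_total) <= p_threshold:
            return x
    return n_fg + 1


def _aligned_identity(a: str, b: str) -> int:
    """Maximal number of identical aligned positions over all offsets and
    both orientations of ``b``."""
    best = 0
    for bb in (b, revcomp(b)):
        for off in range(-(len(bb) - 1), len(a)):
            matches = sum(
                1
                for i in range(max(0, off), min(len(a), off + len(bb)))
                if a[i] == bb[i - off]
            )
            best = max(best, matches)
    return best


def kmer_enrichment(
    fg: FlankSet,
    bg: FlankSet,
    k_range=range(8, 13),
    p_threshold: float = 1e-11,
    collapse_redundant: bool = True,
) -> list[MotifStats]:
    """Exhaustive k-mer enrichment with ZOOPS counting over both strands.

    Every k-mer (canonicalized over strands) is scored by per-sequence
    presence with an upper-tail hypergeometric p against the pooled
    foreground+background population. Motifs at p <= threshold are reported
    after greedy redundancy collapse: of two k-mers sharing >= min(k)-2
    aligned identical positions (any offset/orientation), only the lower-p
    one is kept.
    """
    if not len(fg) or not len(bg):
        raise ValueError("foreground and background must be non-empty")
    overlap = set(fg.flanks) & set(bg.flanks)
    if overlap:
        raise ValueError(f"foreground and background overlap: {sorted(overlap)[:5]}")
    fg_seqs = list(fg.sequences().values())
    bg_seqs = list(bg.sequences().values())
    min_seq_len = min(len(s) for s in fg_seqs + bg_seqs)
    ks = [int(k) for k in k_range]
    if max(ks) > min_seq_len:
        raise ValueError("k exceeds the shortest sequence length")
    n_fg, n_bg = len(fg_seqs), len(bg_seqs)
    n_total = n_fg + n_bg
    k_min = _min_detectable_count(n_fg, n_total, p_threshold)

    candidates: list[MotifStats] = []
    for k in ks:
        fg_counts: dict[str, int] = {}
        for seq in fg_seqs:
            for kmer in _canonical_kmers(seq, k):
                fg_counts[kmer] = fg_counts.get(kmer, 0) + 1
        shortlist = {m: c for m, c in fg_counts.items() if c >= k_min}
        if not shortlist:
            continue
        bg_counts = dict.fromkeys(shortlist, 0)
        for seq in bg_seqs:
            for kmer in _canonical_kmers(seq, k):
                if kmer in bg_counts:
                    bg_counts[kmer] += 1
        for kmer, fgc in shortlist.items():
            bgc = bg_counts[kmer]
            p = hypergeom_upper(fgc, fgc + bgc, n_fg, n_total)
            if p <= p_threshold:
                candidates.append(
                    MotifStats(kmer, fgc, n_fg, bgc, n_bg, p)
                )
    candidates.sort(key=lambda m: (m.p_enrichment, m.motif))
    if not collapse_redundant:
        return candidates
    accepted: list[MotifStats] = []
    for cand in candidates:
        redundant = any(
            _aligned_identity(acc.motif, cand.motif)
            >= min(len(acc.motif), len(cand.motif)) - 2
            for acc in accepted
        )
        if not redundant:
            accepted.append(cand)
    return accepted


def _match_distances(
    motif: str, flanks: FlankSet, both_strands: bool = True
) -> dict[str, int]:
    """Per sequence, the distance of the most CDS-proximal motif occurrence
    to the proximal flank end; sequences without a match are absent."""
    pattern = iupac_pattern(motif)
    rc_pattern = iupac_pattern(revcomp(validate_iupac(motif))) if both_strands else None
    out: dict[str, int] = {}
    for gene, flank in flanks.flanks.items():
        starts = [m.start() for m in pattern.finditer(flank.seq)]
        if rc_pattern is not None and rc_pattern.pattern != pattern.pattern:
            starts += [m.start() for m in rc_pattern.finditer(flank.seq)]
        if starts:
            out[gene] = min(
                flanks.proximal_distance(gene, s, len(motif)) for s in starts
            )
    return out


def positional_bias(motif: str, fg: FlankSet, bg: FlankSet):
    """Positional distributions of a motif in foreground vs background flanks.

    Positions are distances from the motif start to the CDS-proximal flank
    end, one (most proximal) occurrence per sequence. Returns
    (median_fg, median_bg, two-sided two-sample KS p).
    """
    fg_pos = list(_match_distances(motif, fg).values())
    bg_pos = list(_match_distances(motif, bg).values())
    if not fg_pos or not bg_pos:
        raise ValueError("motif must occur at least once in each flank set")
    ks = stats.ks_2samp(fg_pos, bg_pos, alternative="two-sided")
    return float(np.median(fg_pos)), float(np.median(bg_pos)), float(ks.pvalue)


def motif_conservation(
    motif: str, ortholog_flanks: FlankSet, bg_rate: float
) -> tuple[int, int, float]:
    """Conservation of a motif in ortholog flanks against a background rate.

    k = flanks containing the motif (both strands, presence/absence), n =
    total flanks; p = upper-tail binomial P(X >= k | n, bg_rate).
    """
    if not (0 < bg_rate < 1):
        raise ValueError("background rate must lie in (0, 1)")
    n = len(ortholog_flanks)
    if n == 0:
        raise ValueError("empty ortholog flank set")
    k = len(_match_distances(motif, ortholog_flanks))
    p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, bg_rate))
    return k, n, p


def stats_table(results: list[MotifStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in results])
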