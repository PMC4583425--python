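"""Converting alignments and motif lists into count tensors, and evaluation.

The model consumes per-base cleavage (DNase I nick) or transposition (Tn5)
counts in an L-bp window centered on each candidate motif site.  This
module extracts those counts from indexed BAM (or streamed SAM) alignments,
applies the standard site filters (mappability fraction, PWM-score
threshold upstream), builds the ChIP-seq-derived bound/unbound gold
standard used *only* for evaluation, and computes the rank-based AuROC.

Conventions (all configurable where noted):

* coordinates are 0-based half-open throughout; BED passes through as-is;
* windows are centered at ``floor((start + end) / 2)`` and span
  ``[mid - L/2, mid + L/2)``;
* a single-end DNase read contributes one count at its 5' end (leftmost
  aligned base on the plus strand, rightmost on the minus strand);
* ATAC-seq reads get the +4 / -5 Tn5 dimer offset by default;
* minus-strand motif windows are reversed so profiles are motif-oriented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "MotifSite",
    "CountTensor",
    "GoldStandard",
    "read_sites_bed",
    "write_sites_bed",
    "extract_counts",
    "filter_sites",
    "build_gold_standard",
    "compute_auroc",
    "write_posterior_bed",
    "read_posterior_bed",
    "read_counts_tsv",
]

ASSAYS = ("dnase_single_end", "atac_paired_end")


@dataclass
class MotifSite:
    """One candidate binding site (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    pwm_score: float = 0.0
    name: Optional[str] = None
    extra_features: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"site end must exceed start: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def window(self, L: int) -> Tuple[int, int]:
        mid = self.midpoint
        return mid - L // 2, mid - L // 2 + L


@dataclass
class CountTensor:
    """Per-base cut counts, (N sites, S replicates, L bases)."""

    counts: np.ndarray
    sites: List[MotifSite]
    assay: str
    window: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (N, S, L)")
        if self.counts.shape[0] != len(self.sites):
            raise ValueError("row order must match site order")
        L = self.counts.shape[2]
        if L != self.window or (L & (L - 1)) != 0:
            raise ValueError("window must be a power of 2 matching the tensor")

    @property
    def features(self) -> np.ndarray:
        """Site feature matrix for the logistic prior (PWM score + extras)."""
        rows = []
        for s in self.sites:
            row = [s.pwm_score]
            if s.extra_features:
                row.extend(s.extra_features)
            rows.append(row)
        return np.asarray(rows, dtype=float)


def read_sites_bed(path: str, pwm_min: Optional[float] = None) -> List[MotifSite]:
    """Read BED6+ motif sites; numeric columns beyond 6 become extra features.

    ``pwm_min`` optionally drops sites whose score column falls below a
    threshold (the PWM likelihood-ratio cut is normally applied upstream).
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            extra = tuple(float(x) for x in f[6:]) if len(f) > 6 else None
            sites.append(
                MotifSite(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    name=f[3] if len(f) > 3 and f[3] != "." else None,
                    pwm_score=score,
                    strand=f[5] if len(f) > 5 and f[5] in ("+", "-") else "+",
                    extra_features=extra,
                )
            )
    if pwm_min is not None:
        sites = [s for s in sites if s.pwm_score >= pwm_min]
    return sites


def write_sites_bed(path: str, sites: Sequence[MotifSite]):
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            extra = "\t" + "\t".join(map(str, s.extra_features)) if s.extra_features else ""
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name or f'site_{i}'}"
                f"\t{s.pwm_score}\t{s.strand}{extra}\n"
            )


def _cut_position(read, atac_offset: bool) -> int:
    """5' cut/transposition base of an aligned read (0-based)."""
    if read.is_reverse:
        pos = read.reference_end - 1
        if atac_offset:
            pos -= 5
    else:
        pos = read.reference_start
        if atac_offset:
            pos += 4
    return pos


def _extract_one(path, keep_sites, wins, L, mapq_min, atac_offset, strand_mode):
    """Count cuts for one alignment file over pre-validated site windows."""
    import pysam

    n_out = 2 if strand_mode == "separated" else 1
    out = np.zeros((len(keep_sites), n_out, L), dtype=np.int64)

    def add(read, i_site):
        if read.is_unmapped or read.mapping_quality < mapq_min:
            return
        pos = _cut_position(read, atac_offset)
        w0, _ = wins[i_site]
        col = pos - w0
        if not 0 <= col < L:
            return
        site = keep_sites[i_site]
        if site.strand == "-":
            col = L - 1 - col
        if n_out == 1:
            out[i_site, 0, col] += 1
        else:
            # pseudo-replicate 0: reads on the motif strand; 1: opposite
            read_strand = "-" if read.is_reverse else "+"
            out[i_site, 0 if read_strand == site.strand else 1, col] += 1

    with pysam.AlignmentFile(str(path)) as af:
        try:
            has_index = af.has_index()
        except (ValueError, AttributeError):
            has_index = False
        if has_index:
            for i, site in enumerate(keep_sites):
                w0, w1 = wins[i]
                # pad the fetch so minus-strand 5' ends at the window edge are seen
                for read in af.fetch(site.chrom, max(w0 - 10, 0), w1 + 10):
                    add(read, i)
        else:
            from intervaltree import IntervalTree

            trees: Dict[str, IntervalTree] = {}
            for i, site in enumerate(keep_sites):
                w0, w1 = wins[i]
                trees.setdefault(site.chrom, IntervalTree())[w0:w1] = i
            for read in af.fetch(until_eof=True):
                if read.is_unmapped:
                    continue
                tree = trees.get(read.reference_name)
                if tree is None:
                    continue
                pos = _cut_position(read, atac_offset)
                for iv in tree[pos]:
                    add(read, iv.data)
    return out


def extract_counts(alignments: Sequence, sites: Sequence[MotifSite], L: int = 64,
                   assay: str = "dnase_single_end", mapq_min: int = 10,
                   atac_offset: Optional[bool] = None,
                   strand_mode: str = "summed") -> CountTensor:
    """Build the (N, S, L) cut-count tensor from per-replicate alignments.

    ``alignments`` is one path per replicate (BAM with index, or SAM/BAM
    streamed against an interval tree of the site windows).  Sites whose
    window runs off the chromosome are dropped with a warning.  With
    ``strand_mode="separated"`` each alignment file yields two
    pseudo-replicates (motif-strand and opposite-strand cuts) sharing the
    mean profile.
    """
    import pysam

    if assay not in ASSAYS:
        raise ValueError(f"assay must be one of {ASSAYS}")
    if strand_mode not in ("summed", "separated"):
        raise ValueError("strand_mode must be 'summed' or 'separated'")
    if atac_offset is None:
        atac_offset = assay == "atac_paired_end"

    with pysam.AlignmentFile(str(alignments[0])) as af:
        chrom_len = dict(zip(af.references, af.lengths))
    keep_sites, wins = [], []
    n_dropped = 0
    for site in sites:
        w0, w1 = site.window(L)
        clen = chrom_len.get(site.chrom)
        if clen is None or w0 < 0 or w1 > clen:
            n_dropped += 1
            continue
        keep_sites.append(site)
        wins.append((w0, w1))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} site(s) with windows off the chromosome")

    reps = [
        _extract_one(p, keep_sites, wins, L, mapq_min, atac_offset, strand_mode)
        for p in alignments
    ]
    counts = np.concatenate(reps, axis=1) if reps else np.zeros((len(keep_sites), 0, L), int)
    return CountTensor(counts=counts, sites=keep_sites, assay=assay, window=L)


def filter_sites(sites: Sequence[MotifSite],
                 mappability: Optional[Dict[str, np.ndarray]],
                 min_fraction: float = 0.8, window: int = 64) -> List[MotifSite]:
    """Keep sites whose window is at least ``min_fraction`` uniquely mappable.

    ``mappability`` maps chromosome name to a per-base array in [0, 1]
    (pre-computed track); bases beyond the array count as unmappable.  With
    no track the filter is skipped with an explicit warning.
    """
    if mappability is None:
        warnings.warn("no mappability track supplied; mappability filter skipped")
        return list(sites)
    kept = []
    for site in sites:
        w0, w1 = site.window(window)
        track = mappability.get(site.chrom)
        if track is None:
            frac = 0.0
        else:
            seg = np.asarray(track[max(w0, 0): w1], dtype=float)
            frac = float(seg.sum()) / window if len(seg) else 0.0
        if frac >= min_fraction:
            kept.append(site)
    return kept


@dataclass
class GoldStandard:
    """ChIP-seq-derived labels: bound / unbound / ambiguous per site.

    Bound sites overlap a peak; unbound sites overlap no peak *and* have
    fewer depth-normalized ChIP reads than control reads in the evaluation
    window; everything else is ambiguous and excluded from AuROC.
    """

    sites: List[MotifSite]
    labels: np.ndarray  # array of {"bound", "unbound", "ambiguous"}
    chip_count: np.ndarray
    control_count: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        return self.labels != "ambiguous"

    @property
    def y_true(self) -> np.ndarray:
        return (self.labels == "bound").astype(int)

    @property
    def n_ambiguous(self) -> int:
        return int((self.labels == "ambiguous").sum())


def _read_peaks(peaks) -> List[Tuple[str, int, int]]:
    if isinstance(peaks, str):
        out = []
        with open(peaks) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                out.append((f[0], int(f[1]), int(f[2])))
        return out
    return [(c, int(s), int(e)) for c, s, e in peaks]


def build_gold_standard(sites: Sequence[MotifSite], peaks, chip_counts,
                        control_counts, window: int = 400,
                        depth_factors: Optional[Tuple[float, float]] = None
                        ) -> GoldStandard:
    """Label sites against ChIP-seq peaks and depth-normalized read counts.

    ``chip_counts``/``control_counts`` are per-site read counts in the
    ``window``-bp evaluation window around each site; ``depth_factors``
    are the library sizes used for normalization (defaults to the sums of
    the supplied counts).  Duplicate site intervals are dropped with a
    warning, keeping the first occurrence.
    """
    from intervaltree import IntervalTree

    chip = np.asarray(chip_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if len(chip) != len(sites) or len(ctrl) != len(sites):
        raise ValueError("need one chip and control count per site")

    seen = {}
    keep_idx = []
    for i, s in enumerate(sites):
        key = (s.chrom, s.start, s.end, s.strand)
        if key in seen:
            continue
        seen[key] = i
        keep_idx.append(i)
    if len(keep_idx) < len(sites):
        warnings.warn(f"dropped {len(sites) - len(keep_idx)} duplicate site(s)")
    sites = [sites[i] for i in keep_idx]
    chip, ctrl = chip[keep_idx], ctrl[keep_idx]

    if depth_factors is None:
        depth_factors = (max(chip.sum(), 1.0), max(ctrl.sum(), 1.0))
    chip_depth, ctrl_depth = depth_factors

    trees: Dict[str, IntervalTree] = {}
    for c, s, e in _read_peaks(peaks):
        if e > s:
            trees.setdefault(c, IntervalTree())[s:e] = True

    labels = np.empty(len(sites), dtype=object)
    for i, site in enumerate(sites):
        tree = trees.get(site.chrom)
        in_peak = bool(tree is not None and tree.overlap(site.start, site.end))
        if in_peak:
            labels[i] = "bound"
        elif chip[i] / chip_depth < ctrl[i] / ctrl_depth:
            labels[i] = "unbound"
        else:
            labels[i] = "ambiguous"
    return GoldStandard(sites=sites, labels=labels, chip_count=chip, control_count=ctrl)


def compute_auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AuROC with averaged ties.

    ``labels`` may be 0/1, booleans, or the gold-standard strings (in which
    case ambiguous sites are excluded first).
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype == object or labels.dtype.kind in "US":
        keep = labels != "ambiguous"
        scores, labels = scores[keep], labels[keep] == "bound"
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AuROC undefined: need at least one positive and one negative")
    return float(roc_auc_score(y, scores))


def write_posterior_bed(path: str, sites: Sequence[MotifSite], result):
    """Write per-site posterior evidence as BED6+ (tab-separated).

    Columns: chrom, start, end, name, log_posterior_odds, strand,
    posterior_prob, loglik_bound, loglik_unbound.
    """
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tlog_posterior_odds\tstrand"
            "\tposterior_prob\tloglik_bound\tloglik_unbound\n"
        )
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name or f'site_{i}'}"
                f"\t{result.log_posterior_odds[i]:.6g}\t{s.strand}"
                f"\t{result.posterior_prob[i]:.6g}"
                f"\t{result.loglik_bound[i]:.6g}\t{result.loglik_unbound[i]:.6g}\n"
            )


def read_posterior_bed(path: str):
    """Read the BED6+ posterior table back as (sites, columns dict)."""
    sites, odds, prob, llb, llu = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(
                MotifSite(chrom=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                          pwm_score=0.0, strand=f[5])
            )
            odds.append(float(f[4]))
            prob.append(float(f[6]))
            llb.append(float(f[7]))
            llu.append(float(f[8]))
    return sites, {
        "log_posterior_odds": np.array(odds),
        "posterior_prob": np.array(prob),
        "loglik_bound": np.array(llb),
        "loglik_unbound": np.array(llu),
    }


def read_counts_tsv(paths: Sequence[str]) -> np.ndarray:
    """Stack per-replicate N x L count tables into an (N, S, L) tensor."""
    reps = [np.loadtxt(p, dtype=np.int64, ndmin=2) for p in paths]
    shapes = {r.shape for r in reps}
    if len(shapes) != 1:
        raise ValueError(f"replicate count tables disagree in shape: {shapes}")
    return np.stack(reps, axis=1)
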