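"""Quantification of CRISPR/HDR editing outcomes.

Covers the four assay families used to release a gene-corrected cell
product:

* **ddPCR editing efficiency** — the edited-allele probe (FAM)
  concentration relative to a bi-allelic reference probe (HEX), doubled
  under the mono-allelic-edit assumption:
  ``%edited cells = ((FAM * 100) / HEX) * 2``.
* **Competitive ddPCR mutant fraction** — for a mutant/wild-type probe
  pair: ``%cells with mt = ((mt * 100) / (mt + wt)) * 2`` (heterozygous
  carriers assumed), e.g. a 3% mutant allele frequency reads out as 6% of
  cells.
* **Clone genotype gates** — the FAM/HEX ratio of a clonal line falls in
  the mono-allelic band 0.5 +/- 0.19 or the bi-allelic band 1.0 +/- 0.19;
  anything outside is a mixed or incorrectly edited clone.
* **Coupling efficiency** — live enrichment-sorted iSC output over iPS
  cell input, x100; its inversion sizes the iPS cell culture needed for a
  target graft cell dose.
* **Amplicon read classification** — each read is aligned to the
  reference and the donor-repaired (HDR) amplicon; within a quantification
  window covering the cut site and every template-encoded variant, reads
  are labelled unmodified, complete donor integration (all intended
  variants), incomplete donor integration (a strict nonempty subset),
  indel (NHEJ), or ambiguous (no discriminating position covered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from Bio import Align

MONO_BAND = (0.31, 0.69)   # 0.5 +/- 0.19, endpoints inclusive
BI_BAND = (0.81, 1.19)     # 1.0 +/- 0.19

UNMODIFIED = "unmodified"
COMPLETE_DONOR = "complete_donor"
INCOMPLETE_DONOR = "incomplete_donor"
AMBIGUOUS = "ambiguous"
INDEL = "indel"

AMPLICON_LABELS = (UNMODIFIED, COMPLETE_DONOR, INCOMPLETE_DONOR, AMBIGUOUS, INDEL)


class DdpcrResult(NamedTuple):
    percent: float
    assay_inconsistent: bool


def editing_efficiency_pct(fam_copies_per_ul: float, hex_copies_per_ul: float) -> DdpcrResult:
    """Percent heterozygously edited cells from a FAM/HEX ddPCR reaction.

    Mono-allelic edits are assumed, hence the factor 2.  Values above 200%
    are arithmetically possible but biologically impossible and are flagged
    as assay-inconsistent rather than clamped.
    """
    if hex_copies_per_ul <= 0:
        raise ValueError("bi-allelic reference (HEX) concentration must be positive")
    if fam_copies_per_ul < 0:
        raise ValueError("FAM concentration cannot be negative")
    pct = ((fam_copies_per_ul * 100.0) / hex_copies_per_ul) * 2.0
    return DdpcrResult(pct, pct > 200.0)


def ar_mutant_pct(mt_hex: float, wt_fam: float) -> float:
    """Percent of cells carrying the mutant allele in a competitive assay."""
    if mt_hex < 0 or wt_fam < 0:
        raise ValueError("probe concentrations cannot be negative")
    total = mt_hex + wt_fam
    if total <= 0:
        raise ValueError("mt + wt concentration must be positive")
    return ((mt_hex * 100.0) / total) * 2.0


@dataclass
class CloneGenotypeCall:
    ratio: float
    label: str  # "mono" | "bi" | "flagged"


def call_clone_genotype(ratio: float) -> CloneGenotypeCall:
    """Gate a clone's edited/reference ddPCR ratio into mono/bi/flagged."""
    if ratio < 0:
        raise ValueError("ratio cannot be negative")
    if MONO_BAND[0] <= ratio <= MONO_BAND[1]:
        label = "mono"
    elif BI_BAND[0] <= ratio <= BI_BAND[1]:
        label = "bi"
    else:
        label = "flagged"
    return CloneGenotypeCall(ratio=ratio, label=label)


def coupling_efficiency_pct(live_sorted: float, input_cells: float) -> float:
    """%CE = live sorted iSCs / iPS cell input * 100."""
    if input_cells <= 0:
        raise ValueError("input cell count must be positive")
    if live_sorted < 0:
        raise ValueError("sorted cell count cannot be negative")
    return live_sorted / input_cells * 100.0


def required_input(target_cells: float, ce_pct: float) -> int:
    """iPS cell input needed to manufacture ``target_cells`` iSCs at a given
    coupling efficiency, rounded up to a whole cell."""
    if ce_pct <= 0:
        raise ValueError("coupling efficiency must be positive")
    if target_cells < 0:
        raise ValueError("target cell count cannot be negative")
    cells = target_cells / (ce_pct / 100.0)
    # guard against float noise promoting an exact quotient to the next cell
    return math.ceil(cells - 1e-12 * max(1.0, abs(cells)))


def summarize_screen(calls: Iterable[CloneGenotypeCall]) -> dict:
    """Counts per genotype label plus the bi-allelic percentage of a screen."""
    calls = list(calls)
    if not calls:
        raise ValueError("cannot summarize an empty screen")
    counts = {"mono": 0, "bi": 0, "flagged": 0}
    for c in calls:
        counts[c.label] += 1
    total = len(calls)
    return {"counts": counts, "total": total,
            "bi_pct": 100.0 * counts["bi"] / total}


@dataclass
class AmpliconSpec:
    """Reference amplicon, donor-repaired amplicon, and quantification window.

    ``intended_variant_offsets`` are 0-based positions on the reference
    amplicon where the ssODN template encodes a substitution (the
    pathogenic repair plus silent ddPCR-probe mutations); the window is
    half-open in reference coordinates and must cover the cut site and all
    intended variants — the extension beyond the cut-site-centred default
    is what lets incomplete integrations be distinguished.
    """

    ref_amplicon: str
    hdr_amplicon: str
    cut_site: int
    intended_variant_offsets: tuple[int, ...]
    quantification_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.ref_amplicon = self.ref_amplicon.upper()
        self.hdr_amplicon = self.hdr_amplicon.upper()
        if self.ref_amplicon == self.hdr_amplicon:
            raise ValueError("reference and HDR amplicons are identical")
        if len(self.ref_amplicon) != len(self.hdr_amplicon):
            raise ValueError("ref and HDR amplicons must be equal length "
                             "(template encodes substitutions only)")
        lo, hi = self.quantification_window
        if not (0 <= lo < hi <= len(self.ref_amplicon)):
            raise ValueError("quantification window outside the amplicon")
        for off in self.intended_variant_offsets:
            if not (lo <= off < hi):
                raise ValueError(f"intended variant offset {off} outside window [{lo},{hi})")
            if self.ref_amplicon[off] == self.hdr_amplicon[off]:
                raise ValueError(f"offset {off} does not differ between ref and HDR")
        if not (lo <= self.cut_site < hi):
            raise ValueError("cut site outside the quantification window")


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 2
    aln.mismatch_score = -1
    aln.open_gap_score = -5
    aln.extend_gap_score = -1
    return aln


def classify_amplicon_read(read: str, spec: AmpliconSpec) -> str:
    """Classify one amplicon read against the reference/HDR pair.

    The read is globally aligned to the reference amplicon (match 2,
    mismatch -1, gap open -5, gap extend -1).  Within the quantification
    window: any insertion or deletion labels the read ``indel``; otherwise
    the intended variant offsets decide — none installed: ``unmodified``,
    all: ``complete_donor``, a strict subset: ``incomplete_donor``.  A read
    covering no intended offset, with equal best score against reference
    and HDR amplicon, is ``ambiguous``.  Stray substitutions at
    non-discriminating window positions do not change the class.
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    aligner = _aligner()
    ref_aln = aligner.align(read, spec.ref_amplicon)[0]
    lo, hi = spec.quantification_window

    # per-reference-position read base; None = deleted, "" entries never used
    ref_to_read: dict[int, str | None] = {}
    insertion_in_window = False
    read_blocks, ref_blocks = ref_aln.aligned
    prev_read_end = prev_ref_end = None
    for (rstart, rend), (astart, aend) in zip(read_blocks, ref_blocks):
        if prev_ref_end is not None:
            if astart == prev_ref_end and rstart > prev_read_end and lo < astart < hi:
                insertion_in_window = True  # inserted read bases between ref positions
            for gap_pos in range(prev_ref_end, astart):
                ref_to_read[gap_pos] = None  # deleted ref base
        for k in range(aend - astart):
            ref_to_read[astart + k] = read[rstart + k]
        prev_read_end, prev_ref_end = rend, aend

    covered = [p for p in range(lo, hi) if p in ref_to_read]
    deletion_in_window = any(ref_to_read.get(p, "x") is None for p in range(lo, hi))
    if insertion_in_window or deletion_in_window:
        return INDEL

    covered_intended = [p for p in spec.intended_variant_offsets if p in ref_to_read
                        and ref_to_read[p] is not None]
    if not covered_intended:
        hdr_score = aligner.score(read, spec.hdr_amplicon)
        if ref_aln.score == hdr_score or not covered:
            return AMBIGUOUS
        return UNMODIFIED

    installed = sum(1 for p in covered_intended if ref_to_read[p] == spec.hdr_amplicon[p])
    if installed == 0:
        return UNMODIFIED
    if installed == len(spec.intended_variant_offsets):
        return COMPLETE_DONOR
    return INCOMPLETE_DONOR


def classify_reads(reads: Iterable[tuple[str, str]], spec: AmpliconSpec) -> dict:
    """Classify (read_id, sequence) pairs; returns per-read labels and the
    aggregate count/fraction table."""
    per_read: list[tuple[str, str]] = []
    counts = {label: 0 for label in AMPLICON_LABELS}
    for read_id, seq in reads:
        label = classify_amplicon_read(seq, spec)
        per_read.append((read_id, label))
        counts[label] += 1
    total = sum(counts.values())
    fractions = {label: (counts[label] / total if total else 0.0) for label in counts}
    return {"per_read": per_read, "counts": counts, "fractions": fractions, "total": total}
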