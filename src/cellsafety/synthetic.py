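"""Synthetic inputs with ground truth for every stage of the safety analysis.

The generators emulate the statistical structure of the study design — a
three-stage autologous manufacturing lineage (parental fibroblasts ->
iPS cells -> induced skin composites) sequenced at ~40x — without any
sequence realism beyond what the downstream methods consume:

* ``simulate_cohort`` — a variant cohort with five ground-truth classes:
  germline heterozygous (true AF 0.5 everywhere), germline homozygous
  (1.0 everywhere), rare pre-existing somatic (a low AF shared by all
  three stages), clonally amplified (low AF in fibroblasts rising to 0.5
  after single-cell iPSC derivation), and de novo iSC-only (0.5 in iSC
  alone).  Observed AFs are binomial draws at Poisson-distributed depth.
* ``plant_offtarget_sites`` — a random background sequence with planted
  PAM-adjacent 20-mers at controlled Hamming distance from a guide.
* ``simulate_coverage`` — depth tracks with planted heterozygous (x0.5)
  or homozygous (x0) deletions, optionally with binomial depth noise.
* ``simulate_amplicon_reads`` — read mixtures over the donor-integration
  outcome classes with optional uniform substitution noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .editing import AmpliconSpec, COMPLETE_DONOR, INCOMPLETE_DONOR, INDEL, UNMODIFIED
from .offtarget import CoverageTrack, GuideSpec
from .variants import VariantKey

CLASSES = ("germline_het", "germline_hom", "preexisting_somatic",
           "clonally_amplified", "de_novo_isc")

#: Class mix of the default cohort: germline variants dominate a WGS call
#: set, somatic classes are minority events.
DEFAULT_CLASS_COUNTS = {
    "germline_het": 2500,
    "germline_hom": 1000,
    "preexisting_somatic": 800,
    "clonally_amplified": 500,
    "de_novo_isc": 200,
}

_BASES = np.array(list("ACGT"))


@dataclass
class CohortConfig:
    n_variants_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    depth_mean: int = 40
    somatic_af_range: tuple[float, float] = (0.01, 0.30)
    clonal_fibro_af_range: tuple[float, float] = (0.01, 0.20)
    seed: int = 0
    noiseless: bool = False          # depth -> infinity limit: observed AF = true AF
    contig: str = "chrS"
    contig_length: int = 10_000_000

    def __post_init__(self) -> None:
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        for cls, n in self.n_variants_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown variant class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")


#: True AF triple (fibro, iPSC, iSC) per class; None marks the class-specific
#: random component drawn per variant.
def _true_afs(cls: str, rng: np.random.Generator, config: CohortConfig) -> tuple[float, float, float]:
    if cls == "germline_het":
        return (0.5, 0.5, 0.5)
    if cls == "germline_hom":
        return (1.0, 1.0, 1.0)
    if cls == "preexisting_somatic":
        u = rng.uniform(*config.somatic_af_range)
        return (u, u, u)
    if cls == "clonally_amplified":
        u = rng.uniform(*config.clonal_fibro_af_range)
        return (u, 0.5, 0.5)
    if cls == "de_novo_isc":
        return (0.0, 0.0, 0.5)
    raise ValueError(cls)


@dataclass
class CohortSim:
    truth: pd.DataFrame                                   # per-variant class + true AFs
    calls: dict[str, dict[VariantKey, tuple[float, int]]]  # cell type -> called variants
    depth_lookup: dict[str, dict[tuple[str, int], int]]    # covered depth at every locus
    config: CohortConfig

    def truth_keys(self, cls: str) -> set[VariantKey]:
        sub = self.truth[self.truth["class"] == cls]
        return {VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
                for r in sub.itertuples()}


def simulate_cohort(config: CohortConfig | None = None, out_dir: str | None = None) -> CohortSim:
    """Simulate per-cell-type variant calls plus the ground-truth table.

    Observed AF at each locus is Binomial(depth, true AF)/depth with depth
    drawn Poisson(depth_mean) floored at 1; a variant is *called* in a cell
    type iff at least one alternate read was observed, so a truly absent or
    rare allele may legitimately go uncalled — exactly the situation the
    merged table's AF-0 convention handles.  With ``noiseless`` the
    observed AFs equal the true AFs (calls require true AF > 0).

    When ``out_dir`` is given, writes one VCF and one depth track per cell
    type plus ``truth.tsv``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    total = sum(config.n_variants_per_class.values())

    positions = rng.choice(config.contig_length, size=total, replace=False) + 1
    positions.sort()
    ref_idx = rng.integers(0, 4, size=total)
    alt_shift = rng.integers(1, 4, size=total)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    class_of: list[str] = []
    for cls in CLASSES:
        class_of.extend([cls] * config.n_variants_per_class.get(cls, 0))
    order = rng.permutation(total)
    class_arr = np.array(class_of)[order] if total else np.array([], dtype=str)

    rows = []
    calls: dict[str, dict[VariantKey, tuple[float, int]]] = {"fibro": {}, "ipsc": {}, "isc": {}}
    depth_lookup: dict[str, dict[tuple[str, int], int]] = {"fibro": {}, "ipsc": {}, "isc": {}}
    for i in range(total):
        cls = str(class_arr[i])
        key = VariantKey(config.contig, int(positions[i]), str(refs[i]), str(alts[i]))
        true = _true_afs(cls, rng, config)
        row = {"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
               "class": cls, "true_af_fibro": true[0], "true_af_ipsc": true[1],
               "true_af_isc": true[2]}
        for ct, p in zip(("fibro", "ipsc", "isc"), true):
            if config.noiseless:
                depth = config.depth_mean
                af = float(p)
                alt_reads = p * depth
            else:
                depth = max(int(rng.poisson(config.depth_mean)), 1)
                alt_reads = int(rng.binomial(depth, p))
                af = alt_reads / depth
            depth_lookup[ct][(key.chrom, key.pos)] = depth
            row[f"obs_af_{ct}"] = af
            row[f"depth_{ct}"] = depth
            if alt_reads > 0:
                calls[ct][key] = (af, depth)
        rows.append(row)

    truth = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "class",
        "true_af_fibro", "true_af_ipsc", "true_af_isc",
        "obs_af_fibro", "obs_af_ipsc", "obs_af_isc",
        "depth_fibro", "depth_ipsc", "depth_isc"])
    sim = CohortSim(truth=truth, calls=calls, depth_lookup=depth_lookup, config=config)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for ct in ("fibro", "ipsc", "isc"):
            write_vcf(os.path.join(out_dir, f"{ct}.vcf"), calls[ct], sample=ct)
            with open(os.path.join(out_dir, f"{ct}.depth.tsv"), "w") as fh:
                for (chrom, pos), depth in sorted(depth_lookup[ct].items()):
                    fh.write(f"{chrom}\t{pos}\t{depth}\n")
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return sim


def write_vcf(path: str, calls: dict[VariantKey, tuple[float, int]], sample: str = "sample") -> None:
    """Write calls as a minimal single-sample VCF v4.2 with FORMAT AF and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({k.chrom for k in calls}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for key in sorted(calls):
            af, depth = calls[key]
            gt = "1/1" if af > 0.9 else "0/1"
            fh.write(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\t"
                     f"GT:AF:DP\t{gt}:{af:.6g}:{depth}\n")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def plant_offtarget_sites(
    background_length: int,
    planted: list[tuple[int, int, str]],
    guide: GuideSpec | None = None,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Random background with planted protospacer homologies.

    Each planted site ``(offset, mismatches, pam)`` places a 20-mer at
    exactly the requested Hamming distance from the guide, immediately
    followed by the given PAM, on the forward strand.  Sites (20-mer+PAM
    footprints) must not overlap.  Returns the sequence and the truth list.
    """
    guide = guide or GuideSpec()
    rng = np.random.default_rng(seed)
    footprint = 20 + len(guide.pam_pattern)
    spans = sorted((off, off + footprint) for off, _, _ in planted)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"planted sites overlap: [{s1},{e1}) and [{s2},{e2})")
    for off, mm, pam in planted:
        if off < 0 or off + footprint > background_length:
            raise ValueError(f"planted site at {off} outside the background")
        if not (0 <= mm <= 20):
            raise ValueError("mismatch count must be in 0..20")

    seq = list(random_sequence(background_length, rng))
    truth = []
    for off, mm, pam in planted:
        mer = list(guide.protospacer)
        change = rng.choice(20, size=mm, replace=False)
        for pos in change:
            choices = [b for b in "ACGT" if b != mer[pos]]
            mer[pos] = choices[rng.integers(0, 3)]
        site = "".join(mer) + pam.upper()
        seq[off:off + footprint] = site
        truth.append({"offset": off, "mismatches": mm, "pam": pam.upper(),
                      "matched_20mer": "".join(mer), "strand": "+"})
    return "".join(seq), truth


def simulate_coverage(
    length: int,
    chrom_mean: float,
    deletions: list[tuple[int, int, str]] | None = None,
    noise: str = "none",
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[CoverageTrack, list[dict]]:
    """Depth track with planted deletions.

    ``deletions`` is a list of (start, length, zygosity) with zygosity
    "het" (expected depth x0.5) or "hom" (x0); events must not overlap.
    ``noise="binomial"`` draws each base's depth Binomial(2*chrom_mean,
    expected/(2*chrom_mean)), which has the expected mean with
    sequencing-like dispersion; ``"none"`` gives exact expected depth.
    """
    deletions = deletions or []
    if noise not in ("none", "binomial"):
        raise ValueError(f"unknown noise model {noise!r}")
    spans = sorted((s, s + ln) for s, ln, _ in deletions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted deletions overlap")
    expected = np.full(length, float(chrom_mean))
    truth = []
    for start, ln, zyg in deletions:
        if start < 0 or start + ln > length or ln < 1:
            raise ValueError(f"deletion ({start}, {ln}) outside the track")
        if zyg not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {zyg!r}")
        expected[start:start + ln] *= 0.5 if zyg == "het" else 0.0
        truth.append({"start": start, "end": start + ln, "zygosity": zyg})

    if noise == "binomial":
        rng = np.random.default_rng(seed)
        trials = int(round(2 * chrom_mean))
        depth = rng.binomial(trials, expected / trials).astype(float)
    else:
        depth = expected.copy()
    track = CoverageTrack(chrom=chrom, start=0, depth=depth, chrom_mean_depth=float(chrom_mean))
    return track, truth


def write_depth_track(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth):
            fh.write(f"{track.chrom}\t{track.start + i + 1}\t{int(d)}\n")


def default_amplicon_spec(seed: int = 0, length: int = 120) -> AmpliconSpec:
    """A synthetic reference/HDR amplicon pair: four template-encoded
    substitutions (one pathogenic repair, three silent probe mutations)
    around a central cut site, mirroring the assay geometry."""
    rng = np.random.default_rng(seed)
    ref = random_sequence(length, rng)
    cut = length // 2
    offsets = (cut - 12, cut - 4, cut + 3, cut + 11)
    hdr = list(ref)
    for off in offsets:
        hdr[off] = [b for b in "ACGT" if b != ref[off]][rng.integers(0, 3)]
    window = (cut - 20, cut + 20)
    return AmpliconSpec(ref_amplicon=ref, hdr_amplicon="".join(hdr), cut_site=cut,
                        intended_variant_offsets=offsets, quantification_window=window)


def simulate_amplicon_reads(
    spec: AmpliconSpec,
    proportions: dict[str, float],
    n_reads: int,
    substitution_noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Reads drawn from the editing-outcome mixture, with truth labels.

    Class counts follow the proportions deterministically (largest
    remainder), so a noiseless round-trip through the classifier recovers
    them exactly.  Incomplete reads carry a random nonempty strict subset
    of the intended variants; indel reads carry a 1-20 bp insertion or
    deletion at the cut site; noise substitutes bases uniformly at the
    given per-base rate.
    """
    order = (UNMODIFIED, COMPLETE_DONOR, INCOMPLETE_DONOR, INDEL)
    unknown = set(proportions) - set(order)
    if unknown:
        raise ValueError(f"unknown outcome classes {sorted(unknown)}")
    probs = np.array([proportions.get(c, 0.0) for c in order], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {probs.sum()}, expected 1")
    if n_reads < 0:
        raise ValueError("n_reads cannot be negative")

    raw = probs * n_reads
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: n_reads - counts.sum()]:
        counts[idx] += 1

    rng = np.random.default_rng(seed)
    n_intended = len(spec.intended_variant_offsets)
    reads: list[tuple[str, str]] = []
    labels: list[str] = []
    read_no = 0
    for cls, count in zip(order, counts):
        for _ in range(count):
            if cls == UNMODIFIED:
                seq = spec.ref_amplicon
            elif cls == COMPLETE_DONOR:
                seq = spec.hdr_amplicon
            elif cls == INCOMPLETE_DONOR:
                n_install = int(rng.integers(1, n_intended)) if n_intended > 1 else 1
                chosen = rng.choice(n_intended, size=n_install, replace=False)
                s = list(spec.ref_amplicon)
                for ci in chosen:
                    off = spec.intended_variant_offsets[ci]
                    s[off] = spec.hdr_amplicon[off]
                seq = "".join(s)
            else:  # indel at the cut site
                size = int(rng.integers(1, 21))
                if rng.random() < 0.5:
                    ins = random_sequence(size, rng)
                    seq = spec.ref_amplicon[:spec.cut_site] + ins + spec.ref_amplicon[spec.cut_site:]
                else:
                    end = min(spec.cut_site + size, len(spec.ref_amplicon))
                    seq = spec.ref_amplicon[:spec.cut_site] + spec.ref_amplicon[end:]
            if substitution_noise_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(arr.size) < substitution_noise_rate
                for pos in np.flatnonzero(hit):
                    arr[pos] = [b for b in "ACGT" if b != arr[pos]][rng.integers(0, 3)]
                seq = "".join(arr)
            reads.append((f"read_{read_no}", seq))
            labels.append(cls)
            read_no += 1
    return reads, labels


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
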