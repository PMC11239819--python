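"""Multi-caller variant consensus, known-site filtering, region annotation,
and the three-cell-type merged allele-frequency table.

The safety analysis starts from per-caller VCFs for each of the three cell
stages of an autologous product (parental fibroblasts, derived iPS cells,
differentiated induced skin composites).  A variant is accepted only if a
configurable number of callers agree on the identical normalized allele
(chrom, pos, ref, alt); accepted variants matching a known-sites catalogue
(e.g. dbSNP) are removed, the survivors receive a single functional region
category, and the three cell types are merged into one table in which every
variant carries a complete allele-frequency triple
``(af_fibro, af_ipsc, af_isc)`` — an uncalled locus contributes AF 0 at its
covered depth, never a missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

#: Region categories in precedence order (highest first).  A variant hit by
#: several feature intervals gets the highest-precedence category; a variant
#: hit by none is intergenic.
REGION_PRECEDENCE: tuple[str, ...] = (
    "exonic",
    "splice_site",
    "UTR",
    "promoter_enhancer",
    "intronic",
    "intergenic",
)

CELL_TYPES: tuple[str, str, str] = ("fibro", "ipsc", "isc")

MERGED_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "af_fibro", "af_ipsc", "af_isc",
    "depth_fibro", "depth_ipsc", "depth_isc",
    "region", "known",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant identity: 1-based position, atomic ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} at {self.chrom}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in {self}")
        if set(self.ref) - _ACGT or set(self.alt) - _ACGT:
            raise ValueError(f"non-ACGT allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def normalize_key(key: VariantKey, reference: Mapping[str, str] | None = None) -> VariantKey:
    """Reduce a key to its parsimonious representation.

    Shared allele suffix is trimmed first, then shared prefix (keeping at
    least one base of each allele, advancing ``pos`` accordingly) — this
    reconciles the padded InDel representations different callers emit.
    When a ``reference`` (chrom -> sequence, 0-based) is given, InDels are
    additionally left-aligned by shifting while the flanking base allows it.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    seq = reference.get(key.chrom) if reference is not None else None
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif seq is not None and pos > 1:
            # truncate the shared last base and extend left with the
            # preceding reference base (standard left-alignment step)
            prev = seq[pos - 2]
            ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.chrom, pos, ref, alt)


@dataclass
class CallerCallSet:
    """Calls from one variant caller on one cell type, keyed by normalized variant."""

    caller_name: str
    variant_type: str  # "SNV" | "InDel"
    calls: dict[VariantKey, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant_type not in ("SNV", "InDel"):
            raise ValueError(f"variant_type must be SNV or InDel, got {self.variant_type!r}")
        for key, (af, depth) in self.calls.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"AF {af} out of [0,1] for {key} in {self.caller_name}")
            if depth < 0:
                raise ValueError(f"negative depth for {key} in {self.caller_name}")
            if self.variant_type == "SNV" and not key.is_snv:
                raise ValueError(f"non-SNV key {key} in SNV callset {self.caller_name}")


def read_caller_vcf(path: str, caller_name: str, variant_type: str = "SNV",
                    sample_index: int = 0) -> CallerCallSet:
    """Read one caller's VCF into a :class:`CallerCallSet`.

    Multiallelic records are decomposed into biallelic keys.  AF is taken
    from FORMAT ``AF`` when present, otherwise computed as AD_alt/DP; depth
    from FORMAT ``DP``, falling back to INFO ``DP`` then to the AD sum.
    Records whose type does not match ``variant_type`` are skipped, so one
    file may feed both an SNV and an InDel callset.
    """
    from cyvcf2 import VCF

    calls: dict[VariantKey, tuple[float, int]] = {}
    vcf = VCF(path)
    for rec in vcf:
        alts = rec.ALT or []
        for i, alt in enumerate(alts):
            if not alt or set(alt) - _ACGT or set(rec.REF) - _ACGT:
                continue
            key = normalize_key(VariantKey(rec.CHROM, rec.POS, rec.REF, alt))
            want_snv = variant_type == "SNV"
            if key.is_snv != want_snv:
                continue
            af = _format_af(rec, i, sample_index)
            depth = _format_depth(rec, sample_index)
            if af is None:
                ad = rec.format("AD")
                if ad is not None and depth:
                    af = float(ad[sample_index][i + 1]) / depth
                else:
                    raise ValueError(
                        f"{path}: no AF and no AD/DP for {key}; cannot derive allele frequency")
            calls[key] = (min(max(float(af), 0.0), 1.0), int(depth or 0))
    vcf.close()
    return CallerCallSet(caller_name, variant_type, calls)


def _format_af(rec, alt_index: int, sample_index: int):
    try:
        af = rec.format("AF")
    except KeyError:
        af = None
    if af is None:
        return None
    row = af[sample_index]
    try:
        return float(row[min(alt_index, len(row) - 1)])
    except TypeError:
        return float(row)


def _format_depth(rec, sample_index: int) -> int:
    try:
        dp = rec.format("DP")
    except KeyError:
        dp = None
    if dp is not None:
        return int(dp[sample_index][0])
    info_dp = rec.INFO.get("DP")
    if info_dp is not None:
        return int(info_dp)
    ad = rec.format("AD")
    if ad is not None:
        return int(sum(ad[sample_index]))
    return 0


def read_known_sites(path: str) -> set[VariantKey]:
    """Known-sites VCF (e.g. a dbSNP extract) as a set of normalized keys."""
    from cyvcf2 import VCF

    known: set[VariantKey] = set()
    vcf = VCF(path)
    for rec in vcf:
        for alt in rec.ALT or []:
            if not alt or set(alt) - _ACGT or set(rec.REF) - _ACGT:
                continue
            known.add(normalize_key(VariantKey(rec.CHROM, rec.POS, rec.REF, alt)))
    vcf.close()
    return known


def intersect_callers(
    callsets: Sequence[CallerCallSet],
    min_callers: int | None = None,
    primary_caller: str | None = None,
) -> dict[VariantKey, tuple[float, int]]:
    """Multi-caller consensus: keep keys reported by at least ``min_callers``.

    Defaults to full overlap (all callers agree), the rule used to call a
    variant "true" in the safety assessment.  AF/depth of a consensus key
    are taken from the designated primary caller (default: the first
    listed); if that caller lacks the key, the mean over reporting callers
    is used.
    """
    if not callsets:
        raise ValueError("callsets must be nonempty")
    vtypes = {cs.variant_type for cs in callsets}
    if len(vtypes) > 1:
        raise ValueError(f"mixed variant types in consensus: {sorted(vtypes)}")
    if min_callers is None:
        min_callers = len(callsets)
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    if min_callers > len(callsets):
        raise ValueError("min_callers exceeds number of callsets")

    primary = callsets[0]
    if primary_caller is not None:
        by_name = {cs.caller_name: cs for cs in callsets}
        if primary_caller not in by_name:
            raise ValueError(f"primary caller {primary_caller!r} not among callsets")
        primary = by_name[primary_caller]

    support: dict[VariantKey, int] = {}
    for cs in callsets:
        for key in cs.calls:
            support[key] = support.get(key, 0) + 1

    consensus: dict[VariantKey, tuple[float, int]] = {}
    for key, n in support.items():
        if n < min_callers:
            continue
        if key in primary.calls:
            consensus[key] = primary.calls[key]
        else:
            rows = [cs.calls[key] for cs in callsets if key in cs.calls]
            af = sum(r[0] for r in rows) / len(rows)
            depth = round(sum(r[1] for r in rows) / len(rows))
            consensus[key] = (af, depth)
    return consensus


def filter_known_sites(
    variants: Mapping[VariantKey, tuple[float, int]],
    known: Iterable[VariantKey],
) -> dict[VariantKey, tuple[float, int]]:
    """Drop variants whose exact key (chrom, pos, ref, alt) is a known site."""
    known_set = set(known)
    return {k: v for k, v in variants.items() if k not in known_set}


def read_features_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read feature intervals from 6-column BED; category sits in the name field."""
    features = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: need >= 4 BED columns")
            chrom, start, end, category = parts[0], int(parts[1]), int(parts[2]), parts[3]
            features.append((chrom, start, end, category))
    return features


def annotate_regions(
    keys: Iterable[VariantKey],
    features: Sequence[tuple[str, int, int, str]],
) -> dict[VariantKey, str]:
    """Assign exactly one region category per variant by precedence.

    Feature intervals are 0-based half-open (BED); variant positions are
    1-based (VCF), so a variant at pos p tests containment of p-1.
    """
    rank = {cat: i for i, cat in enumerate(REGION_PRECEDENCE)}
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, category in features:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} ({category})")
        if category not in rank:
            raise ValueError(f"unknown region category {category!r} at {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, category)

    out: dict[VariantKey, str] = {}
    for key in keys:
        tree = trees.get(key.chrom)
        hits = tree[key.pos - 1] if tree is not None else ()
        if hits:
            out[key] = min((iv.data for iv in hits), key=rank.__getitem__)
        else:
            out[key] = "intergenic"
    return out


def read_depth_track(path: str) -> dict[tuple[str, int], int]:
    """Per-base depth as a (chrom, 1-based pos) -> depth map from a TSV track."""
    depths: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos, depth = line.split("\t")[:3]
            depths[(chrom, int(pos))] = int(depth)
    return depths


def merge_cell_types(
    fibro: Mapping[VariantKey, tuple[float, int]],
    ipsc: Mapping[VariantKey, tuple[float, int]],
    isc: Mapping[VariantKey, tuple[float, int]],
    depth_lookup: Mapping[str, Mapping[tuple[str, int], int]] | None = None,
    regions: Mapping[VariantKey, str] | None = None,
    known: Iterable[VariantKey] | None = None,
) -> pd.DataFrame:
    """Merge the three filtered consensus sets into one analysis table.

    One row per key in the union.  A cell type that did not call a variant
    contributes AF 0 at the covered depth from ``depth_lookup`` (depth 0 and
    a log line when no lookup covers the locus).  The resulting complete AF
    triples are what the specificity analyses consume.
    """
    known_set = set(known) if known is not None else set()
    per_type = {"fibro": fibro, "ipsc": ipsc, "isc": isc}
    union = sorted(set().union(*[set(m) for m in per_type.values()]))

    rows = []
    for key in union:
        row: dict[str, object] = {
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
        }
        for ct in CELL_TYPES:
            calls = per_type[ct]
            if key in calls:
                af, depth = calls[key]
            else:
                af = 0.0
                depth = None
                if depth_lookup is not None and ct in depth_lookup:
                    depth = depth_lookup[ct].get((key.chrom, key.pos))
                if depth is None:
                    logger.warning("no depth for uncalled locus %s:%d in %s; depth set 0",
                                   key.chrom, key.pos, ct)
                    depth = 0
            row[f"af_{ct}"] = float(af)
            row[f"depth_{ct}"] = int(depth)
        row["region"] = regions.get(key, "intergenic") if regions is not None else "intergenic"
        row["known"] = key in known_set
        rows.append(row)
    return pd.DataFrame(rows, columns=MERGED_COLUMNS)


def write_merged_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_merged_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MERGED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing merged-table columns {sorted(missing)}")
    return table


def table_keys(table: pd.DataFrame) -> list[VariantKey]:
    """Recover VariantKeys from merged-table rows, preserving row order."""
    return [VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in table.itertuples()]
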