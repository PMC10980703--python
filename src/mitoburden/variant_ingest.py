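"""Ingest per-sample variant tables from the two callers and apply the
consensus acceptance rules.

The study design calls mtDNA variants twice per sample: once with a
mutserve-based read-level pipeline ("PCP") whose limit of detection reaches
well below 10% variant level (VL), and once with the sequencer vendor's
caller ("TSS") whose limit of detection is 10%. Acceptance rules:

* a PCP variant with VL >= 10% is kept only when TSS reports the same
  (position, alt) — dual-caller consensus;
* a PCP variant with VL < 10% and no TSS match may be *rescued* when all
  four read-level reliability indicators pass their thresholds **and** the
  variant is present in a curated allow-list of previously reported mtDNA
  variants;
* a PCP variant with VL < 10% that TSS happens to confirm is kept;
* TSS-only variants are never accepted.

Sample-level sequencing QC: mean coverage >= 1500 reads/bp and coverage
uniformity >= 85%; failing samples are flagged for resequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .region_map import GENOME_LENGTH

CONSENSUS_VL_THRESHOLD = 0.10
MT_CONTIGS = {"chrM", "chrMT", "MT", "M", "NC_012920.1", "rCRS"}

#: columns of the accepted-variant frame produced by :func:`consensus_frame`
VARIANT_COLUMNS = [
    "pos", "ref", "alt", "vl", "support", "in_curated_db",
    "norm_cov", "cov_ratio", "numt_mean", "edge_dist",
]


class IngestError(ValueError):
    """Malformed caller output."""


@dataclass(frozen=True)
class CallerRecord:
    sample_id: str
    pos: int
    ref: str
    alt: str
    vl: float
    caller: str  # "PCP" | "TSS"
    norm_cov: float = math.nan
    cov_ratio: float = math.nan
    numt_mean: float = math.nan
    edge_dist: float = math.nan

    def __post_init__(self) -> None:
        if not 1 <= self.pos <= GENOME_LENGTH:
            raise IngestError(f"position {self.pos} outside rCRS")
        if not 0.0 <= self.vl <= 1.0:
            raise IngestError(f"variant level {self.vl} outside [0, 1]")
        if self.alt == self.ref:
            raise IngestError(f"alt equals ref at {self.pos}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.pos, self.alt)


@dataclass(frozen=True)
class ConsensusVariant:
    """One accepted variant; VL and quality fields come from the PCP record."""

    pos: int
    ref: str
    alt: str
    vl: float
    support: str  # "both" | "pcp_only_rescued"
    in_curated_db: bool = False
    norm_cov: float = math.nan
    cov_ratio: float = math.nan
    numt_mean: float = math.nan
    edge_dist: float = math.nan

    @property
    def key(self) -> tuple[int, str]:
        return (self.pos, self.alt)


@dataclass(frozen=True)
class RescueThresholds:
    """Reliability-indicator thresholds for rescuing sub-10%-VL variants.

    Defaults are this package's documented choices; they are configurable
    because upstream pipelines publish their own calibrations.
    """

    min_norm_cov: float = 0.5
    min_cov_ratio: float = 0.5
    max_cov_ratio: float = 2.0
    max_numt_mean: float = 1.0
    min_edge_dist: float = 5.0

    def passes(self, rec: CallerRecord) -> bool:
        vals = (rec.norm_cov, rec.cov_ratio, rec.numt_mean, rec.edge_dist)
        if any(math.isnan(v) for v in vals):
            return False
        return (
            rec.norm_cov >= self.min_norm_cov
            and self.min_cov_ratio <= rec.cov_ratio <= self.max_cov_ratio
            and rec.numt_mean <= self.max_numt_mean
            and rec.edge_dist >= self.min_edge_dist
        )


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    mean_coverage: float
    coverage_uniformity: float

    @property
    def qc_pass(self) -> bool:
        return self.coverage_uniformity >= 0.85 and self.mean_coverage >= 1500

    @property
    def action(self) -> str:
        return "ok" if self.qc_pass else "resequence"


def sample_qc(sample_id: str, mean_coverage: float, coverage_uniformity: float) -> SampleQC:
    if mean_coverage < 0 or coverage_uniformity < 0:
        raise IngestError("coverage metrics must be non-negative")
    return SampleQC(sample_id, mean_coverage, coverage_uniformity)


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and trim an allele pair so cross-caller keys agree.

    Shared suffix is removed first, then shared prefix (advancing ``pos``);
    at least one base is kept on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# parsers

_COLUMN_ALIASES = {
    "sample": "sample_id", "sample_id": "sample_id", "id": "sample_id",
    "pos": "pos", "position": "pos",
    "ref": "ref",
    "alt": "alt", "variant": "alt",
    "vl": "vl", "variantlevel": "vl", "variant_level": "vl",
    "vl_percent": "vl_percent", "variantlevel_percent": "vl_percent",
    "norm_cov": "norm_cov", "cov_ratio": "cov_ratio",
    "numt_mean": "numt_mean", "edge_dist": "edge_dist",
}


def parse_pcp_table(path: str | Path, sample_id: str | None = None) -> list[CallerRecord]:
    """Parse a mutserve-style tab-separated variant table.

    The VL column is a fraction under the names ``vl``/``VariantLevel``; a
    ``_percent`` suffix on the column name, or a literal ``%`` in a value,
    marks percent input (divided by 100). Malformed rows are reported with
    their 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c: _COLUMN_ALIASES.get(c.strip().lower()) for c in df.columns}
    df = df.rename(columns={c: a for c, a in cols.items() if a})
    vl_is_percent = "vl_percent" in df.columns
    if vl_is_percent:
        df = df.rename(columns={"vl_percent": "vl"})
    needed = {"pos", "ref", "alt", "vl"}
    if sample_id is None:
        needed = needed | {"sample_id"}
    missing = needed - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing mandatory columns {sorted(missing)}")

    records: list[CallerRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            raw_vl = str(row.vl).strip()
            percent = vl_is_percent or raw_vl.endswith("%")
            vl = float(raw_vl.rstrip("%"))
            if percent:
                vl /= 100.0
            pos, ref, alt = normalize_allele(
                int(row.pos), str(row.ref).strip(), str(row.alt).strip()
            )
            records.append(
                CallerRecord(
                    sample_id=sample_id or str(row.sample_id),
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    vl=vl,
                    caller="PCP",
                    norm_cov=_opt_float(row, "norm_cov"),
                    cov_ratio=_opt_float(row, "cov_ratio"),
                    numt_mean=_opt_float(row, "numt_mean"),
                    edge_dist=_opt_float(row, "edge_dist"),
                )
            )
        except (IngestError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise IngestError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return records


def _opt_float(row, name: str) -> float:
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return math.nan
    val = str(val).strip()
    return float(val) if val else math.nan


def parse_tss_vcf(path: str | Path, sample_id: str | None = None) -> list[CallerRecord]:
    """Parse a VCF 4.x from the vendor caller into per-(pos, alt) records.

    Multiallelic sites are split; the AF INFO field (or the first sample's
    FORMAT AF) maps to VL. Any non-mitochondrial contig is an error.
    """
    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    records: list[CallerRecord] = []
    for var in vcf:
        if var.CHROM not in MT_CONTIGS:
            raise IngestError(f"{path}: non-mitochondrial contig {var.CHROM!r}")
        afs = var.INFO.get("AF")
        if afs is None and "AF" in (var.FORMAT or []):
            afs = tuple(np.asarray(var.format("AF")[0], dtype=float))
        if afs is None:
            afs = (math.nan,) * len(var.ALT)
        if not isinstance(afs, (tuple, list, np.ndarray)):
            afs = (afs,)
        for alt, af in zip(var.ALT, afs):
            pos, ref, alt_n = normalize_allele(var.POS, var.REF, alt)
            vl = float(af) if af is not None and not math.isnan(float(af)) else 1.0
            records.append(
                CallerRecord(sample_id=sample_id, pos=pos, ref=ref, alt=alt_n,
                             vl=vl, caller="TSS")
            )
    return records


# ---------------------------------------------------------------------------
# consensus filter

@dataclass
class FilterLog:
    """Tallies of the filter's drop decisions for one sample."""

    kept_both: int = 0
    kept_rescued: int = 0
    dropped_high_vl_no_tss: int = 0
    dropped_low_vl_failed_rescue: int = 0
    tss_only_ignored: int = 0


def consensus_filter(
    pcp: Iterable[CallerRecord],
    tss: Iterable[CallerRecord],
    rescue: RescueThresholds | None = None,
    curated_db: set[tuple[int, str]] | frozenset[tuple[int, str]] = frozenset(),
) -> tuple[list[ConsensusVariant], FilterLog]:
    """Apply the dual-caller acceptance rules to one sample.

    Returns the accepted variants (always a subset of the PCP input, keyed by
    (pos, alt)) and a log of drop counts. Filtering is total: no input is an
    error.
    """
    rescue = rescue or RescueThresholds()
    pcp = list(pcp)
    tss_keys = {r.key for r in tss}
    log = FilterLog(tss_only_ignored=len({r.key for r in tss} - {r.key for r in pcp}))

    kept: list[ConsensusVariant] = []
    for rec in pcp:
        in_db = rec.key in curated_db
        confirmed = rec.key in tss_keys
        if confirmed:
            support = "both"
            log.kept_both += 1
        elif rec.vl < CONSENSUS_VL_THRESHOLD and rescue.passes(rec) and in_db:
            support = "pcp_only_rescued"
            log.kept_rescued += 1
        else:
            if rec.vl >= CONSENSUS_VL_THRESHOLD:
                log.dropped_high_vl_no_tss += 1
            else:
                log.dropped_low_vl_failed_rescue += 1
            continue
        kept.append(
            ConsensusVariant(
                pos=rec.pos, ref=rec.ref, alt=rec.alt, vl=rec.vl,
                support=support, in_curated_db=in_db,
                norm_cov=rec.norm_cov, cov_ratio=rec.cov_ratio,
                numt_mean=rec.numt_mean, edge_dist=rec.edge_dist,
            )
        )
    return kept, log


def consensus_frame(variants: Iterable[ConsensusVariant]) -> pd.DataFrame:
    """Accepted variants as a DataFrame (the pipeline's working container)."""
    rows = [
        {
            "pos": v.pos, "ref": v.ref, "alt": v.alt, "vl": v.vl,
            "support": v.support, "in_curated_db": v.in_curated_db,
            "norm_cov": v.norm_cov, "cov_ratio": v.cov_ratio,
            "numt_mean": v.numt_mean, "edge_dist": v.edge_dist,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return df.astype({"pos": int, "vl": float})


def load_allowlist(path: str | Path | None = None) -> set[tuple[int, str]]:
    """Curated allow-list TSV with columns pos, ref, alt → {(pos, alt)}.

    ``path=None`` loads the bundled *synthetic* stand-in list (fabricated
    entries for tests and demos); real analyses should pass a database
    export.
    """
    if path is None:
        from importlib import resources

        source = resources.files("mitoburden.data") / "allowlist_synthetic.tsv"
        with resources.as_file(source) as p:
            return load_allowlist(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pos": int, "alt": str})
    if not {"pos", "alt"} <= set(df.columns):
        raise IngestError(f"{path}: allow-list needs columns pos, alt")
    return {(int(p), str(a)) for p, a in zip(df["pos"], df["alt"])}
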