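"""Genotype, interval and table I/O for the AIM design pipeline.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  Every
  internal interval-membership test uses the BED convention (a variant at
  1-based position ``pos`` is tested at point ``pos - 1``).
* Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with
  ``NaN`` for missing.  Any genotype containing a ``.`` allele (including
  half-calls such as ``0/.``) is missing.
* Multi-allelic records are retained on read but flagged, so that the
  biallelic-only filter can drop them later.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SampleMap",
    "GenotypeMatrix",
    "RegionSet",
    "VcfParseError",
    "SampleLookupError",
    "read_vcf_genotypes",
    "write_vcf",
    "apply_variant_filters",
    "extract_panel_genotypes",
    "read_panel_table",
    "write_genotype_tsv",
    "read_genotype_tsv",
]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


class SampleLookupError(KeyError):
    """Raised when a requested sample is absent from a VCF header or map."""


@dataclass(frozen=True)
class VariantKey:
    """A biallelic (or flagged multi-allelic) variant locus.

    ``alt`` holds the comma-joined ALT field for multi-allelic records.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # used as column label in TSV output
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class SampleMap:
    """Mapping of sample id to population label (plus optional subpopulation)."""

    populations: dict[str, str]
    subpopulations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, pop in self.populations.items():
            if not pop:
                raise ValueError(f"empty population label for sample {sid!r}")

    def population(self, sample: str) -> str:
        try:
            return self.populations[sample]
        except KeyError:
            raise SampleLookupError(f"sample {sample!r} not in sample map") from None

    def population_labels(self) -> list[str]:
        """Distinct population labels in sorted order."""
        return sorted(set(self.populations.values()))

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.populations.items() if p == population]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMap":
        """Read a 2–3 column headered TSV: sample_id, population[, subpopulation]."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"sample map {path} needs >= 2 columns")
        sid, pop = df.columns[0], df.columns[1]
        if df[sid].duplicated().any():
            dupes = df.loc[df[sid].duplicated(), sid].tolist()
            raise ValueError(f"duplicate sample ids in {path}: {dupes}")
        pops = dict(zip(df[sid], df[pop]))
        subs: dict[str, str] = {}
        if df.shape[1] >= 3:
            sub = df.columns[2]
            subs = {s: v for s, v in zip(df[sid], df[sub]) if isinstance(v, str)}
        return cls(populations=pops, subpopulations=subs)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (s, p, self.subpopulations.get(s, ""))
            for s, p in self.populations.items()
        ]
        pd.DataFrame(rows, columns=["sample_id", "population", "subpopulation"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    ``dosages`` is ``float64`` with entries in {0, 1, 2} and ``NaN`` for
    missing calls; shape ``(n_samples, n_variants)``.
    """

    samples: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray
    multiallelic: np.ndarray  # bool, per variant

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.multiallelic = np.asarray(self.multiallelic, dtype=bool)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        if self.multiallelic.shape != (len(self.variants),):
            raise ValueError("multiallelic flag length mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"non-dosage values present: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return np.isnan(self.dosages).mean(axis=0)

    def take_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            dosages=self.dosages[:, index],
            multiallelic=self.multiallelic[index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise SampleLookupError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in names]
        return GenotypeMatrix(
            samples=list(names),
            variants=list(self.variants),
            dosages=self.dosages[idx, :],
            multiallelic=self.multiallelic.copy(),
        )

    def is_position_sorted(self) -> bool:
        """True when variants form per-chromosome runs with ascending positions."""
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for v in self.variants:
            if v.chrom != prev_chrom:
                if v.chrom in seen:
                    return False  # chromosome re-appears after a switch
                seen.add(v.chrom)
                prev_chrom, prev_pos = v.chrom, v.pos
            else:
                if v.pos < prev_pos:
                    return False
                prev_pos = v.pos
        return True


@dataclass
class RegionSet:
    """Set of genomic intervals (0-based half-open) with overlap-safe membership."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        return cls(trees=trees)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"BED line with < 3 fields in {path}: {line!r}")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based point."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos0, pos0 + 1))

    def contains_variant(self, key: VariantKey) -> bool:
        return self.contains(key.chrom, key.pos - 1)


def _dosage_from_alleles(alleles: Sequence[int], alt_index: int | None = None) -> float:
    """Dosage from integer allele calls; any negative (missing) allele -> NaN.

    With ``alt_index`` None, counts any non-reference allele (the biallelic
    reading; multi-allelic records are flagged and normally filtered out).
    """
    if any(a < 0 for a in alleles):
        return np.nan
    if alt_index is None:
        return float(sum(1 for a in alleles if a > 0))
    return float(sum(1 for a in alleles if a == alt_index))


def read_vcf_genotypes(
    path: str | Path, samples: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read a VCF 4.x file (plain or bgzipped) into a GenotypeMatrix.

    Phased (``|``) and unphased (``/``) separators are both accepted; any
    genotype containing ``.`` becomes missing.  Multi-allelic records are
    retained with their flag set.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        header = VCF(path)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    header_samples = list(header.samples)
    header.close()

    if samples is not None:
        absent = [s for s in samples if s not in header_samples]
        if absent:
            raise SampleLookupError(f"samples not in VCF header of {path}: {absent}")
        vcf = VCF(path, samples=list(samples))
        out_samples = list(samples)
    else:
        vcf = VCF(path)
        out_samples = header_samples
    # cyvcf2 returns columns in header order; remember how to reorder
    col_order = {s: i for i, s in enumerate(vcf.samples)}
    reorder = [col_order[s] for s in out_samples]

    keys: list[VariantKey] = []
    multi: list[bool] = []
    rows: list[np.ndarray] = []
    try:
        for i, rec in enumerate(vcf):
            alts = rec.ALT if rec.ALT else ["."]
            if alts == ["."]:
                continue  # monomorphic record, no alternate allele to count
            keys.append(
                VariantKey(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=",".join(alts),
                    id=rec.ID or ".",
                )
            )
            multi.append(len(alts) > 1)
            dos = np.array(
                [_dosage_from_alleles(g[:-1]) for g in rec.genotypes], dtype=float
            )
            rows.append(dos[reorder])
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record near #{len(keys) + 1} in {path}: {exc}"
        ) from exc
    finally:
        vcf.close()

    dosages = (
        np.column_stack(rows) if rows else np.empty((len(out_samples), 0))
    )
    return GenotypeMatrix(
        samples=out_samples,
        variants=keys,
        dosages=dosages,
        multiallelic=np.array(multi, dtype=bool),
    )


def _gt_string(d: float, n_alleles: int = 2) -> str:
    if np.isnan(d):
        return "./."
    d = int(d)
    return "/".join(["1"] * d + ["0"] * (n_alleles - d))[::-1]  # e.g. 1 -> "0/1"


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Serialize a GenotypeMatrix as an unphased plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in g.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, v in enumerate(g.variants):
            gts = "\t".join(_gt_string(d) for d in g.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def apply_variant_filters(
    g: GenotypeMatrix,
    regions: RegionSet | None = None,
    biallelic_only: bool = False,
    max_missing_fraction: float = 1.0,
) -> GenotypeMatrix:
    """Apply region, biallelic and missingness filters to a genotype matrix.

    A variant is removed iff its missing fraction is *strictly* greater than
    ``max_missing_fraction`` (a 10 % threshold keeps a variant at exactly
    10 % missing).  Sample order is preserved; the operation is idempotent
    and the individual filters commute.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = np.ones(g.n_variants, dtype=bool)
    if regions is not None:
        keep &= np.array([regions.contains_variant(v) for v in g.variants], dtype=bool)
    if biallelic_only:
        keep &= ~g.multiallelic
    keep &= g.missing_fraction() <= max_missing_fraction
    if not keep.any():
        warnings.warn("all variants removed by filters", stacklevel=2)
    return g.take_variants(np.flatnonzero(keep))


def _panel_keys(panel) -> list[VariantKey]:
    """Accept an AimPanel, a DataFrame with chrom/pos/ref/alt columns, or keys."""
    if hasattr(panel, "variant_keys"):
        return list(panel.variant_keys)
    if isinstance(panel, pd.DataFrame):
        return [
            VariantKey(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                id=str(getattr(r, "id", ".")),
            )
            for r in panel.itertuples(index=False)
        ]
    return list(panel)


def read_panel_table(path: str | Path) -> pd.DataFrame:
    """Read a panel TSV written by :mod:`exaim.panel_design`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel table {path} lacks columns {required - set(df.columns)}")
    return df


def extract_panel_genotypes(
    calls: str | Path, panel, min_depth: int = 2
) -> GenotypeMatrix:
    """Extract panel-marker dosages from a WES variant-call VCF.

    One output column per panel marker, in panel order.  A marker absent
    from the calls, covered below ``min_depth`` (FORMAT/DP), or with alleles
    incompatible with the panel yields missing.  REF/ALT orientation is
    reconciled against the panel: dosage always counts the panel's alternate
    allele, so a swapped record contributes ``2 - dosage``.
    """
    from cyvcf2 import VCF

    keys = _panel_keys(panel)
    wanted: dict[tuple[str, int], list[int]] = {}
    for j, k in enumerate(keys):
        wanted.setdefault((k.chrom, k.pos), []).append(j)

    vcf = VCF(str(calls))
    samples = list(vcf.samples)
    out = np.full((len(samples), len(keys)), np.nan)
    try:
        for rec in vcf:
            hits = wanted.get((rec.CHROM, rec.POS))
            if hits is None:
                continue
            alts = rec.ALT if rec.ALT else []
            try:
                dp = rec.format("DP")
            except KeyError:  # DP absent from the header entirely
                dp = None
            depths = dp[:, 0] if dp is not None else None  # None: DP not reported
            for j in hits:
                key = keys[j]
                alt_index: int | None = None
                swapped = False
                if rec.REF == key.ref and key.alt in alts:
                    alt_index = alts.index(key.alt) + 1
                elif rec.REF == key.alt and key.ref in alts and len(alts) == 1:
                    swapped = True
                elif rec.REF == key.ref and not alts:
                    alt_index = -999  # record is monomorphic ref: dosage 0 if called
                else:
                    logger.warning(
                        "alleles at %s:%d (%s>%s) incompatible with panel %s>%s; "
                        "marker set missing",
                        rec.CHROM, rec.POS, rec.REF, ",".join(alts) or ".",
                        key.ref, key.alt,
                    )
                    continue
                for i, g in enumerate(rec.genotypes):
                    if min_depth > 0 and (depths is None or depths[i] < min_depth):
                        continue  # unknown or shallow coverage stays missing
                    alleles = g[:-1]
                    if any(a < 0 for a in alleles):
                        continue
                    if alt_index == -999:
                        out[i, j] = 0.0
                    elif swapped:
                        out[i, j] = 2.0 - float(sum(1 for a in alleles if a == 1))
                    else:
                        out[i, j] = float(sum(1 for a in alleles if a == alt_index))
    finally:
        vcf.close()

    return GenotypeMatrix(
        samples=samples,
        variants=keys,
        dosages=out,
        multiallelic=np.zeros(len(keys), dtype=bool),
    )


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV: rows samples, columns ``chrom:pos:ref:alt``."""
    df = pd.DataFrame(
        g.dosages, index=pd.Index(g.samples, name="sample_id"),
        columns=[str(v) for v in g.variants],
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    keys = []
    for col in df.columns:
        chrom, pos, ref, alt = col.rsplit(":", 3)
        keys.append(VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        variants=keys,
        dosages=df.to_numpy(dtype=float),
        multiallelic=np.zeros(len(keys), dtype=bool),
    )
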