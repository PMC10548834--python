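"""Somatic variant I/O, normalization, and retention filtering.

Variant identity is the backbone of every downstream comparison: two tumors
"share" a mutation iff their normalized (chrom, pos, ref, alt) keys are equal.
This module reads calls from VCF or a MAF-like TSV, canonicalizes keys so the
intersection is representation-independent, and applies the somatic retention
predicate: at least 4 variant-supporting reads, variant allele fraction >= 2%,
population allele frequency <= 1%, and absence from a user-supplied blacklist
of recurrent sequencing errors.

Conventions
-----------
* Coordinates are 1-based (VCF); indels carry an anchor base before trimming.
* Chromosome names are canonicalized: a leading ``chr`` is stripped, the name
  is uppercased, and ``M`` is unified to ``MT``.
* Population frequency in VCF input is the maximum over the INFO fields
  ``POP_AF``, ``MAX_AF``, ``AF_1000G``, ``AF_EXAC`` (missing => 0).
* Synonymous status in VCF input comes from the INFO flag ``SYN`` when
  present; otherwise calls are treated as non-synonymous.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MutationKey",
    "SomaticCall",
    "MutationProfile",
    "VariantFormatError",
    "read_variants",
    "read_profile",
    "normalize_mutation_key",
    "normalize_key",
    "filter_somatic_calls",
    "write_profile",
]

_ACGT = frozenset("ACGT")
_POP_AF_FIELDS = ("POP_AF", "MAX_AF", "AF_1000G", "AF_EXAC")

#: MAF-like TSV column order (tab-delimited, UTF-8, "." for missing).
MAF_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "alt_reads",
    "depth",
    "vaf",
    "non_synonymous",
    "pop_freq",
    "blacklisted",
)


class VariantFormatError(ValueError):
    """A record could not be parsed under the declared format."""


def canonical_chrom(name: str) -> str:
    """Canonicalize a chromosome name for cross-file comparability."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    return s


def _chrom_order(chrom: str) -> tuple[int, str]:
    """Sort key placing numeric chromosomes first, in numeric order."""
    return (0, f"{int(chrom):02d}") if chrom.isdigit() else (1, chrom)


@dataclass(frozen=True)
class MutationKey:
    """Identity of a somatic variant.

    Equality and hashing use only (chrom, pos, ref, alt); ``gene`` and
    ``protein_change`` are annotations carried along for reporting.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ACGT:
                raise ValueError(f"{name} must be a non-empty ACGT string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationKey):
            return NotImplemented
        return (self.chrom, self.pos, self.ref, self.alt) == (
            other.chrom,
            other.pos,
            other.ref,
            other.alt,
        )

    def __hash__(self) -> int:
        return hash((self.chrom, self.pos, self.ref, self.alt))

    def sort_key(self) -> tuple:
        return (*_chrom_order(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SomaticCall:
    """One called somatic variant with its read support and annotations.

    ``vaf`` may be omitted (None): it is then computed as alt_reads/depth.
    A provided ``vaf`` must agree with alt_reads/depth to within 0.01 when
    depth > 0.
    """

    key: MutationKey
    depth: int
    alt_reads: int
    vaf: float | None = None
    pop_freq: float = 0.0
    non_synonymous: bool = True
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq must be in [0, 1], got {self.pop_freq}")
        if self.vaf is None:
            computed = self.alt_reads / self.depth if self.depth > 0 else 0.0
            object.__setattr__(self, "vaf", computed)
        else:
            if not 0.0 <= self.vaf <= 1.0:
                raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
            if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.01:
                raise ValueError(
                    f"vaf {self.vaf:.4f} inconsistent with "
                    f"alt_reads/depth = {self.alt_reads}/{self.depth}"
                )


@dataclass(frozen=True)
class MutationProfile:
    """One sample's retained somatic calls, keyed by normalized identity."""

    sample_id: str
    calls: tuple[SomaticCall, ...]
    patient_id: str | None = None
    timepoint: str | None = None
    histology: str | None = None

    def __post_init__(self) -> None:
        keys = [c.key for c in self.calls]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate MutationKeys in profile {self.sample_id}")

    def keys(self) -> frozenset[MutationKey]:
        return frozenset(c.key for c in self.calls)

    def nonsyn_keys(self) -> frozenset[MutationKey]:
        return frozenset(c.key for c in self.calls if c.non_synonymous)

    def __len__(self) -> int:
        return len(self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationProfile):
            return NotImplemented
        return self.sample_id == other.sample_id and set(self.calls) == set(other.calls)

    def __hash__(self) -> int:
        return hash((self.sample_id, frozenset(self.calls)))


# ---------------------------------------------------------------------------
# normalization


def normalize_mutation_key(key: MutationKey) -> MutationKey:
    """Return the canonical representative of a variant's identity.

    Shared trailing bases are trimmed first, then shared leading bases, each
    while both alleles keep at least one base; the position advances by one
    per leading base removed. SNVs are already minimal and pass unchanged.
    Idempotent by construction.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (key.ref, key.alt, key.pos):
        return key
    return replace(key, pos=pos, ref=ref, alt=alt)


def normalize_key(call: SomaticCall) -> SomaticCall:
    """Normalize a call's mutation key (see :func:`normalize_mutation_key`)."""
    norm = normalize_mutation_key(call.key)
    return call if norm is call.key else replace(call, key=norm)


# ---------------------------------------------------------------------------
# reading


def _parse_missing(value, default=None):
    if value is None:
        return default
    s = str(value).strip()
    return default if s in {".", "", "nan", "None"} else s


def _read_vcf(path: str | Path) -> list[SomaticCall]:
    from cyvcf2 import VCF

    calls: list[SomaticCall] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VariantFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            gene = _parse_missing(rec.INFO.get("GENE"))
            pchange = _parse_missing(rec.INFO.get("PCHANGE"))
            non_syn = not bool(rec.INFO.get("SYN", False))
            pop_freq = max(
                (float(rec.INFO.get(f)) for f in _POP_AF_FIELDS if rec.INFO.get(f) is not None),
                default=0.0,
            )
            # read support: per-sample AD (ref, alt1, alt2, ...) preferred,
            # else FORMAT AF + DP, else INFO DP alone.
            ad = None
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            afs = None
            if ad is None:
                try:
                    afs = rec.format("AF")
                except KeyError:
                    afs = None
            depths = None
            try:
                depths = rec.format("DP")
            except KeyError:
                depths = None
            for i, alt in enumerate(rec.ALT):
                if alt is None or not set(alt) <= _ACGT:
                    continue  # symbolic / spanning-deletion alleles are not somatic SNV/indel calls
                key = MutationKey(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=gene,
                    protein_change=pchange,
                )
                if ad is not None:
                    row = [int(x) for x in ad[0] if x >= 0]
                    alt_reads = int(ad[0][i + 1])
                    depth = int(sum(row))
                    vaf = None
                elif afs is not None and depths is not None:
                    depth = int(depths[0][0] if hasattr(depths[0], "__len__") else depths[0])
                    af = float(afs[0][i] if hasattr(afs[0], "__len__") else afs[0])
                    alt_reads = int(round(af * depth))
                    vaf = af
                else:
                    depth = int(rec.INFO.get("DP", 0))
                    alt_reads = 0
                    vaf = None
                calls.append(
                    SomaticCall(
                        key=key,
                        depth=depth,
                        alt_reads=alt_reads,
                        vaf=vaf,
                        pop_freq=pop_freq,
                        non_synonymous=non_syn,
                    )
                )
    except VariantFormatError:
        raise
    except Exception as exc:
        raise VariantFormatError(
            f"{path}: malformed VCF record #{record_no + 1}: {exc}"
        ) from exc
    return calls


_BOOL_TRUE = {"true", "1", "yes", "t"}


def _read_maf_tsv(path: str | Path) -> list[SomaticCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    except Exception as exc:
        raise VariantFormatError(f"{path}: cannot parse as MAF-like TSV: {exc}") from exc
    required = {"chrom", "pos", "ref", "alt", "alt_reads", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise VariantFormatError(f"{path}: missing required columns {sorted(missing)}")
    calls: list[SomaticCall] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            key = MutationKey(
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene=_parse_missing(d.get("gene")),
                protein_change=_parse_missing(d.get("protein_change")),
            )
            vaf_raw = _parse_missing(d.get("vaf"))
            nonsyn_raw = _parse_missing(d.get("non_synonymous"), "true")
            pop_raw = _parse_missing(d.get("pop_freq"), "0")
            black_raw = _parse_missing(d.get("blacklisted"), "false")
            calls.append(
                SomaticCall(
                    key=key,
                    depth=int(d["depth"]),
                    alt_reads=int(d["alt_reads"]),
                    vaf=None if vaf_raw is None else float(vaf_raw),
                    pop_freq=float(pop_raw),
                    non_synonymous=str(nonsyn_raw).lower() in _BOOL_TRUE,
                    blacklisted=str(black_raw).lower() in _BOOL_TRUE,
                )
            )
        except (ValueError, KeyError) as exc:
            raise VariantFormatError(f"{path}: malformed record at line {line_no}: {exc}") from exc
    return calls


def read_variants(path: str | Path, format: str = "vcf") -> list[SomaticCall]:
    """Read somatic calls from ``path``.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"vcf", "maf_tsv"}
        ``vcf`` reads VCF 4.x (multi-allelic records are split, one call per
        alternate allele); ``maf_tsv`` reads the tab-delimited layout written
        by :func:`write_profile`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "maf_tsv":
        return _read_maf_tsv(path)
    raise VariantFormatError(f"unknown format tag {format!r} (expected 'vcf' or 'maf_tsv')")


def read_profile(path: str | Path, **meta) -> MutationProfile:
    """Read a MAF-like TSV written by :func:`write_profile` back into a profile.

    The sample id is taken from the file's ``sample_id`` column (all rows must
    agree); ``meta`` may supply patient_id/timepoint/histology.
    """
    calls = _read_maf_tsv(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_ids = set(df["sample_id"]) if "sample_id" in df.columns and len(df) else set()
    if len(sample_ids) > 1:
        raise VariantFormatError(f"{path}: multiple sample_ids {sorted(sample_ids)}")
    sample_id = meta.pop("sample_id", None) or (sample_ids.pop() if sample_ids else "sample")
    return MutationProfile(sample_id=sample_id, calls=tuple(calls), **meta)


# ---------------------------------------------------------------------------
# filtering


def filter_somatic_calls(
    calls: Iterable[SomaticCall],
    min_alt_reads: int = 4,
    min_vaf: float = 0.02,
    max_pop_freq: float = 0.01,
    *,
    blacklist: Iterable[MutationKey] | None = None,
    sample_id: str = "sample",
    patient_id: str | None = None,
    timepoint: str | None = None,
    histology: str | None = None,
) -> MutationProfile:
    """Apply the somatic retention predicate and build a profile.

    A call is retained iff alt_reads >= ``min_alt_reads`` AND
    vaf >= ``min_vaf`` (both boundaries inclusive) AND
    pop_freq <= ``max_pop_freq`` (exclusion is strictly above the threshold)
    AND the call is not blacklisted. Keys are normalized first; duplicate keys
    collapse to the call with maximal alt_reads (ties: maximal depth).
    """
    blackset = frozenset(normalize_mutation_key(k) for k in (blacklist or ()))
    best: dict[MutationKey, SomaticCall] = {}
    for call in calls:
        call = normalize_key(call)
        if call.alt_reads < min_alt_reads:
            continue
        if call.vaf < min_vaf:
            continue
        if call.pop_freq > max_pop_freq:
            continue
        if call.blacklisted or call.key in blackset:
            continue
        prev = best.get(call.key)
        if prev is None or (call.alt_reads, call.depth) > (prev.alt_reads, prev.depth):
            best[call.key] = call
    ordered = tuple(sorted(best.values(), key=lambda c: c.key.sort_key()))
    return MutationProfile(
        sample_id=sample_id,
        calls=ordered,
        patient_id=patient_id,
        timepoint=timepoint,
        histology=histology,
    )


# ---------------------------------------------------------------------------
# writing


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_profile(profile: MutationProfile, path: str | Path) -> Path:
    """Write a profile as a MAF-like TSV that round-trips via read_variants."""
    path = Path(path)
    lines = ["\t".join(MAF_COLUMNS)]
    for c in sorted(profile.calls, key=lambda c: c.key.sort_key()):
        k = c.key
        lines.append(
            "\t".join(
                _fmt(v)
                for v in (
                    profile.sample_id,
                    k.chrom,
                    k.pos,
                    k.ref,
                    k.alt,
                    k.gene,
                    k.protein_change,
                    c.alt_reads,
                    c.depth,
                    c.vaf,
                    c.non_synonymous,
                    c.pop_freq,
                    c.blacklisted,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
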