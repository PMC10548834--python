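"""MHC class-I neoantigen enumeration, strong-binder calling, and sharing.

Each non-synonymous mutation is represented by a mutant peptide context: up to
21 residues with the altered residue at position 11 (1-based), shorter when
the mutation falls near a protein terminus. Candidate epitopes are all 9- to
11-mer sliding windows that contain the mutated residue; windows that do not
are wild-type peptides and are never enumerated. A window binding any of the
patient's HLA class-I alleles with predicted IC50 strictly below 500 nM is a
strong binder, and all strong windows from one mutation collapse into a
single countable neoantigen.

The binding predictor is pluggable: any callable ``(peptide, allele) -> nM``.
The bundled :func:`mock_affinity` is a deterministic stand-in used by the
synthetic cohort; :class:`TabularPredictor` adapts the TSV output of an
external predictor (columns peptide, allele, ic50_nM).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

from .variant_io import MutationKey

__all__ = [
    "STRONG_BINDER_NM",
    "HLAGenotype",
    "PeptideContext",
    "PeptideWindow",
    "NeoantigenCall",
    "NeoantigenReport",
    "SharedNeoantigenSummary",
    "enumerate_windows",
    "mock_affinity",
    "TabularPredictor",
    "call_neoantigens",
    "shared_neoantigens",
    "read_hla",
    "read_contexts_fasta",
    "write_contexts_fasta",
    "write_neoantigen_tsv",
]

#: strong-binder threshold; selection is strict (< 500 nM, ties excluded)
STRONG_BINDER_NM = 500.0

WINDOW_LENGTHS = (9, 10, 11)
FULL_CONTEXT_LENGTH = 21
FULL_MUT_INDEX = 11  # 1-based center of a full-length context

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_HLA_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2,3}$")
_MOTIF_RE = re.compile(r"W[ILV]F")


@dataclass(frozen=True)
class HLAGenotype:
    """A patient's class-I alleles in 4-digit nomenclature (HLA-A*02:01)."""

    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("HLA genotype needs at least one allele")
        seen: list[str] = []
        for a in self.alleles:
            if not _HLA_RE.match(a):
                raise ValueError(f"not a 4-digit class-I allele name: {a!r}")
            if a not in seen:
                seen.append(a)
        if len(seen) > 6:
            raise ValueError("more than 6 class-I alleles")
        object.__setattr__(self, "alleles", tuple(seen))


@dataclass(frozen=True)
class PeptideContext:
    """Mutant peptide context for one non-synonymous mutation."""

    key: MutationKey
    sequence: str
    mut_index: int  # 1-based position of the mutated residue

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValueError(f"invalid amino-acid sequence {self.sequence!r}")
        if len(self.sequence) > FULL_CONTEXT_LENGTH:
            raise ValueError("context longer than 21 residues")
        if not 1 <= self.mut_index <= len(self.sequence):
            raise ValueError(
                f"mut_index {self.mut_index} outside sequence of length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """One candidate epitope overlapping the mutated residue."""

    peptide: str
    key: MutationKey
    start: int  # 1-based start within the context
    contains_mut: bool = True


@dataclass(frozen=True)
class NeoantigenCall:
    """All strong-binder evidence for one mutation, counted as one neoantigen."""

    key: MutationKey
    strong_windows: tuple[tuple[str, str, float], ...]  # (peptide, allele, ic50_nM)

    def __post_init__(self) -> None:
        if not self.strong_windows:
            raise ValueError("a NeoantigenCall requires >= 1 strong window")
        if any(ic50 >= STRONG_BINDER_NM for _, _, ic50 in self.strong_windows):
            raise ValueError("strong windows must all have IC50 < 500 nM")

    @property
    def best_ic50(self) -> float:
        return min(ic50 for _, _, ic50 in self.strong_windows)


@dataclass(frozen=True)
class NeoantigenReport:
    """Collapsed calls for one sample plus bookkeeping on skipped keys."""

    sample_id: str
    calls: tuple[NeoantigenCall, ...]
    n_missing_contexts: int = 0
    skipped_keys: tuple[MutationKey, ...] = ()

    def keys(self) -> frozenset[MutationKey]:
        return frozenset(c.key for c in self.calls)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class SharedNeoantigenSummary:
    """Neoantigen sharing between two samples, at the mutation level."""

    sample_a: str
    sample_b: str
    n_shared: int
    n_a: int
    n_b: int
    pct_of_a: float
    pct_of_b: float
    undefined_a: bool = False  # sample a had zero neoantigens
    undefined_b: bool = False


def enumerate_windows(ctx: PeptideContext) -> list[PeptideWindow]:
    """All 9/10/11-mer substrings of the context containing the mutated residue.

    Order is deterministic: length ascending, then start ascending. Contexts
    shorter than 9 residues yield no windows.
    """
    seq, mut = ctx.sequence, ctx.mut_index
    n = len(seq)
    windows: list[PeptideWindow] = []
    for length in WINDOW_LENGTHS:
        lo = max(1, mut - length + 1)
        hi = min(mut, n - length + 1)
        for start in range(lo, hi + 1):
            windows.append(
                PeptideWindow(
                    peptide=seq[start - 1 : start - 1 + length],
                    key=ctx.key,
                    start=start,
                )
            )
    return windows


def mock_affinity(peptide: str, allele: str) -> float:
    """Deterministic stand-in binding predictor.

    Pure function of (peptide, allele): peptides containing the planted motif
    ``W[ILV]F`` score 50 nM (strong) against every allele; all others score
    5000 nM. Used by the synthetic cohort so that planted binders are the only
    strong binders.
    """
    if not 9 <= len(peptide) <= 11:
        raise ValueError(f"peptide length must be 9-11, got {len(peptide)}")
    if not set(peptide) <= AMINO_ACIDS:
        raise ValueError(f"invalid amino-acid symbols in {peptide!r}")
    return 50.0 if _MOTIF_RE.search(peptide) else 5000.0


class TabularPredictor:
    """Adapter for an external predictor's tabular output.

    Reads a TSV with columns ``peptide``, ``allele``, ``ic50_nM`` and serves
    lookups; pairs absent from the table score ``default`` nM (weak). This is
    how e.g. netMHCpan-style output is ingested without re-running it.
    """

    def __init__(self, path: str | Path, default: float = 50000.0):
        self.default = float(default)
        self._table: dict[tuple[str, str], float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"peptide", "allele", "ic50_nM"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected columns {sorted(required)}")
            for row in reader:
                self._table[(row["peptide"], row["allele"])] = float(row["ic50_nM"])

    def __call__(self, peptide: str, allele: str) -> float:
        return self._table.get((peptide, allele), self.default)


def call_neoantigens(
    profile,
    contexts: Mapping[MutationKey, PeptideContext],
    hla: HLAGenotype,
    predictor: Callable[[str, str], float] = mock_affinity,
) -> NeoantigenReport:
    """Score every mutant window against every allele and collapse per mutation.

    For each non-synonymous retained key in the profile: enumerate the
    mutation-containing windows, score each against each allele, keep
    (peptide, allele) pairs with IC50 strictly below 500 nM, and emit at most
    one :class:`NeoantigenCall` per key. Keys without a context are skipped
    with a warning and counted in the report.
    """
    calls: list[NeoantigenCall] = []
    skipped: list[MutationKey] = []
    for key in sorted(profile.nonsyn_keys(), key=lambda k: k.sort_key()):
        ctx = contexts.get(key)
        if ctx is None:
            skipped.append(key)
            continue
        strong: list[tuple[str, str, float]] = []
        for window in enumerate_windows(ctx):
            for allele in hla.alleles:
                ic50 = float(predictor(window.peptide, allele))
                if ic50 < STRONG_BINDER_NM:
                    strong.append((window.peptide, allele, ic50))
        if strong:
            calls.append(NeoantigenCall(key=key, strong_windows=tuple(strong)))
    if skipped:
        warnings.warn(
            f"{profile.sample_id}: {len(skipped)} non-synonymous mutation(s) "
            "without a peptide context were skipped",
            stacklevel=2,
        )
    return NeoantigenReport(
        sample_id=profile.sample_id,
        calls=tuple(calls),
        n_missing_contexts=len(skipped),
        skipped_keys=tuple(skipped),
    )


def shared_neoantigens(
    a: NeoantigenReport, b: NeoantigenReport, *, level: str = "mutation"
) -> SharedNeoantigenSummary:
    """Sharing summary between two samples' collapsed neoantigen calls.

    ``level='mutation'`` (default) counts mutations with a strong binder in
    both samples; ``level='peptide'`` is a stricter toggle requiring the same
    strong peptide string in both. A sample with zero neoantigens gets 0%
    with its ``undefined_`` flag set rather than a division by zero.
    """
    if level == "mutation":
        set_a: frozenset = a.keys()
        set_b: frozenset = b.keys()
    elif level == "peptide":
        set_a = frozenset(p for c in a.calls for p, _, _ in c.strong_windows)
        set_b = frozenset(p for c in b.calls for p, _, _ in c.strong_windows)
    else:
        raise ValueError(f"unknown sharing level {level!r}")
    n_shared = len(set_a & set_b)
    n_a, n_b = len(set_a), len(set_b)
    return SharedNeoantigenSummary(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_shared=n_shared,
        n_a=n_a,
        n_b=n_b,
        pct_of_a=100.0 * n_shared / n_a if n_a else 0.0,
        pct_of_b=100.0 * n_shared / n_b if n_b else 0.0,
        undefined_a=n_a == 0,
        undefined_b=n_b == 0,
    )


# ---------------------------------------------------------------------------
# I/O


def read_hla(path: str | Path) -> HLAGenotype:
    """Read an HLA genotype from a text file, one allele name per line."""
    alleles = [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return HLAGenotype(alleles=tuple(alleles))


def _context_header(ctx: PeptideContext) -> str:
    k = ctx.key
    return f"{k.chrom}|{k.pos}|{k.ref}|{k.alt}|{ctx.mut_index}"


def write_contexts_fasta(
    contexts: Mapping[MutationKey, PeptideContext] | Iterable[PeptideContext],
    path: str | Path,
) -> Path:
    """Write peptide contexts as FASTA with ``chrom|pos|ref|alt|mut_index`` headers."""
    if isinstance(contexts, Mapping):
        records = contexts.values()
    else:
        records = contexts
    ordered = sorted(records, key=lambda c: c.key.sort_key())
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for ctx in ordered:
            fh.write(f">{_context_header(ctx)}\n{ctx.sequence}\n")
    return path


def read_contexts_fasta(path: str | Path) -> dict[MutationKey, PeptideContext]:
    contexts: dict[MutationKey, PeptideContext] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 5:
            raise ValueError(
                f"{path}: header {record.id!r} is not chrom|pos|ref|alt|mut_index"
            )
        chrom, pos, ref, alt, mut_index = parts
        key = MutationKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
        contexts[key] = PeptideContext(
            key=key, sequence=str(record.seq), mut_index=int(mut_index)
        )
    return contexts


def write_neoantigen_tsv(reports: Sequence[NeoantigenReport], path: str | Path) -> Path:
    path = Path(path)
    lines = ["sample_id\tchrom\tpos\tref\talt\tgene\tbest_ic50\tn_strong_windows"]
    for rep in reports:
        for c in rep.calls:
            k = c.key
            lines.append(
                f"{rep.sample_id}\t{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}"
                f"\t{k.gene or '.'}\t{c.best_ic50:.1f}\t{len(c.strong_windows)}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
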