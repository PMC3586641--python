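"""SNP discovery between aligned homologous fragments of two strains.

Two near-identical sequences per fragment are globally aligned; every
differing column yields a SNP call classified as transition, transversion
or indel.  A contiguous run of gap columns counts as ONE indel event by
default (single insertion/deletion mutations commonly span several
nucleotides), with per-column counting available via ``indel_mode``.
Columns containing N are excluded from both site and SNP counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
ALPHABET = set("ACGTN-")


@dataclass
class AlignedFragmentPair:
    """A gapped alignment of one fragment from two strains."""

    fragment_id: str
    seq_a: str
    seq_b: str
    source_strains: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b) or len(self.seq_a) < 1:
            raise ValueError("aligned sequences must have equal length >= 1")
        bad = (set(self.seq_a) | set(self.seq_b)) - ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
        for i, (x, y) in enumerate(zip(self.seq_a, self.seq_b)):
            if x == "-" and y == "-":
                raise ValueError(f"column {i + 1} is gap in both sequences")

    def __len__(self) -> int:
        return len(self.seq_a)


@dataclass
class SNPRecord:
    fragment_id: str
    column: int  # 1-based alignment column (start of run for indels)
    snp_class: str  # "transition" | "transversion" | "indel"
    states: tuple[str, str]


@dataclass
class SNPSummary:
    """Aggregate SNP statistics over a set of fragments."""

    per_fragment_sites: dict[str, int]
    per_fragment_snps: dict[str, int]
    per_fragment_percent: dict[str, float]
    total_sites: int
    total_snps: int
    transitions: int
    transversions: int
    indels: int
    overall_percent: float
    ti_tv_ratio: float

    def __post_init__(self) -> None:
        if self.transitions + self.transversions + self.indels != self.total_snps:
            raise ValueError("class counts do not sum to total SNPs")


def classify_substitution(x: str, y: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    pair = {x, y}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


# ----------------------------------------------------------------------
# Global alignment (Needleman-Wunsch, linear gap)
# ----------------------------------------------------------------------

@dataclass
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def align_pair(
    a: str,
    b: str,
    params: AlignmentParams | None = None,
    fragment_id: str = "pair",
    source_strains: tuple[str, str] = ("a", "b"),
) -> AlignedFragmentPair:
    """Optimal global alignment of two sequences under linear gap scoring.

    Ties are broken deterministically: diagonal (match/mismatch) is
    preferred, then a gap in `b` (consuming `a`), then a gap in `a`.
    Suited to near-identical fragments; quadratic in sequence length.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    p = params or AlignmentParams()
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * p.gap
    score[:, 0] = np.arange(n + 1) * p.gap
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    sub = np.where(arr_a[:, None] == arr_b[None, :], p.match, p.mismatch)
    for i in range(1, n + 1):
        # vectorised over j is unsafe (row depends on itself); keep the
        # inner loop but hoist constants
        row_prev = score[i - 1]
        row = score[i]
        srow = sub[i - 1]
        for j in range(1, m + 1):
            row[j] = max(row_prev[j - 1] + srow[j - 1],
                         row_prev[j] + p.gap,
                         row[j - 1] + p.gap)
    # traceback with the stated preference order
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + p.gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return AlignedFragmentPair(
        fragment_id=fragment_id,
        seq_a="".join(reversed(out_a)),
        seq_b="".join(reversed(out_b)),
        source_strains=source_strains,
    )


def alignment_score(pair: AlignedFragmentPair, params: AlignmentParams | None = None) -> float:
    p = params or AlignmentParams()
    s = 0.0
    for x, y in zip(pair.seq_a, pair.seq_b):
        if x == "-" or y == "-":
            s += p.gap
        elif x == y:
            s += p.match
        else:
            s += p.mismatch
    return s


# ----------------------------------------------------------------------
# SNP calling and aggregation
# ----------------------------------------------------------------------

def call_snps(pair: AlignedFragmentPair, indel_mode: str = "run") -> list[SNPRecord]:
    """One record per differing column (columns with N skipped).

    With ``indel_mode="run"`` (default) each maximal run of gap columns
    on the same sequence yields a single indel record anchored at the
    run's first column, with the gapped side reported as ``"-"``; with
    ``"column"`` every gap column is its own record.
    """
    if indel_mode not in ("run", "column"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    records: list[SNPRecord] = []
    i = 0
    L = len(pair)
    a, b = pair.seq_a, pair.seq_b
    while i < L:
        x, y = a[i], b[i]
        if x == "N" or y == "N":
            i += 1
            continue
        if x == "-" or y == "-":
            gap_in_a = x == "-"
            j = i
            while j < L and ((a[j] == "-") if gap_in_a else (b[j] == "-")) \
                    and (b[j] != "N" if gap_in_a else a[j] != "N"):
                j += 1
            if indel_mode == "run":
                seg = (b if gap_in_a else a)[i:j]
                states = ("-", seg) if gap_in_a else (seg, "-")
                records.append(SNPRecord(pair.fragment_id, i + 1, "indel", states))
            else:
                for k in range(i, j):
                    states = ("-", b[k]) if gap_in_a else (a[k], "-")
                    records.append(SNPRecord(pair.fragment_id, k + 1, "indel", states))
            i = j
        elif x != y:
            records.append(
                SNPRecord(pair.fragment_id, i + 1, classify_substitution(x, y), (x, y))
            )
            i += 1
        else:
            i += 1
    return records


def site_count(pair: AlignedFragmentPair) -> int:
    """Alignment columns usable as sites: those without N in either row."""
    return sum(
        1 for x, y in zip(pair.seq_a, pair.seq_b) if x != "N" and y != "N"
    )


def summarize_snps(
    records: dict[str, list[SNPRecord]],
    lengths: dict[str, int],
) -> SNPSummary:
    """Aggregate per-fragment SNP calls into totals and percentages.

    `lengths` gives the number of compared sites per fragment; the
    overall frequency is 100 x total SNPs / total sites.
    """
    total_sites = sum(lengths.values())
    if total_sites <= 0:
        raise ValueError("zero total compared sites")
    per_snps = {f: len(records.get(f, [])) for f in lengths}
    for f, c in per_snps.items():
        if lengths[f] < c:
            raise ValueError(f"fragment {f}: more SNPs ({c}) than sites ({lengths[f]})")
    classes = [r.snp_class for recs in records.values() for r in recs]
    ti = classes.count("transition")
    tv = classes.count("transversion")
    ind = classes.count("indel")
    total = ti + tv + ind
    return SNPSummary(
        per_fragment_sites=dict(lengths),
        per_fragment_snps=per_snps,
        per_fragment_percent={
            f: 100.0 * per_snps[f] / lengths[f] if lengths[f] else 0.0 for f in lengths
        },
        total_sites=total_sites,
        total_snps=total,
        transitions=ti,
        transversions=tv,
        indels=ind,
        overall_percent=100.0 * total / total_sites,
        ti_tv_ratio=ti / tv if tv else float("inf"),
    )


def read_fragment_fasta(path, fragment_id: str | None = None) -> AlignedFragmentPair:
    """Read a two-sequence FASTA of pre-aligned (or equal-length) fragments."""
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 2:
        raise ValueError(f"{path}: expected exactly 2 sequences, found {len(recs)}")
    return AlignedFragmentPair(
        fragment_id=fragment_id or recs[0].id,
        seq_a=str(recs[0].seq),
        seq_b=str(recs[1].seq),
        source_strains=(recs[0].id, recs[1].id),
    )
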