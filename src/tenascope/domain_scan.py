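"""Builtin domain detection and architecture assembly.

The centrepiece is the tenascin-type EGF-like domain scanner, which encodes
the family's diagnostic cysteine/glycine spacing

    x C x(3) C x(5) C x(4-6) C x C x(5) G x(2) C x

where x is any residue *except* cysteine (the pattern's information content is
the cysteine spacing, so spacer positions must not re-use cysteines).  Strict
mode allows 4-6 residues between the third and fourth cysteines; relaxed mode
extends that spacer to 8, which admits the divergent EGF-like domains seen in
hemichordate tenascin-like proteins.

FN3 and FReD detection is a reference-profile stand-in for an external domain
service: sliding windows are screened by edit-distance identity against
packaged exemplars and candidate hits are confirmed with the BLOSUM62 global
aligner.  Pipelines meant to mirror database annotations should supply an
EXTERNAL domain table, which always takes precedence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from ._exemplars import FN3_EXEMPLARS, FRED_TEMPLATES
from .records import (
    AnnotationMethod,
    Architecture,
    DomainAnnotation,
    DomainKind,
    ProteinRecord,
)

log = logging.getLogger(__name__)

#: residues counted as hydrophobic by the signal-peptide heuristic
_SIGNAL_HYDROPHOBIC = frozenset("AILMFVWC")

#: FReD must end within this many residues of the C-terminus to count as
#: carboxy-terminal; small predicted tails are common in real proteomes.
TERMINAL_FRED_WINDOW = 30


# ------------------------------------------------------------ EGF consensus

@dataclass(frozen=True)
class EgfConsensus:
    """Tenascin-type EGF spacing pattern as (residue-class, min, max) segments.

    Residue classes: "x" = any residue but C; "C" and "G" are literal.
    Exactly one segment (the C3-C4 spacer) is variable.
    """

    segments: tuple = (
        ("x", 1, 1), ("C", 1, 1), ("x", 3, 3), ("C", 1, 1), ("x", 5, 5),
        ("C", 1, 1), ("x", 4, 6), ("C", 1, 1), ("x", 1, 1), ("C", 1, 1),
        ("x", 5, 5), ("G", 1, 1), ("x", 2, 2), ("C", 1, 1), ("x", 1, 1),
    )
    relaxed_max_c3c4: int = 8

    def segments_for(self, mode: str) -> list[tuple[str, int, int]]:
        if mode not in ("strict", "relaxed"):
            raise ValueError(f"unknown scan mode {mode!r}")
        segs = list(self.segments)
        if mode == "relaxed":
            cls, lo, hi = segs[6]
            segs[6] = (cls, lo, max(hi, self.relaxed_max_c3c4))
        return segs

    def span(self, mode: str) -> tuple[int, int]:
        segs = self.segments_for(mode)
        return (sum(s[1] for s in segs), sum(s[2] for s in segs))


DEFAULT_EGF_CONSENSUS = EgfConsensus()


def _match_at(seq: str, i: int, segs, var_index: int) -> int | None:
    """Length of the longest consensus instance starting at 0-based ``i``,
    or None.  Longest-first over the single variable spacer."""
    cls, lo, hi = segs[var_index]
    for k in range(hi, lo - 1, -1):
        pos = i
        ok = True
        for s, (c, a, b) in enumerate(segs):
            n = k if s == var_index else a
            chunk = seq[pos:pos + n]
            if len(chunk) < n:
                ok = False
                break
            if c == "x":
                if "C" in chunk:
                    ok = False
                    break
            elif chunk != c * n:
                ok = False
                break
            pos += n
        if ok:
            return pos - i
    return None


def scan_egf_tenascin(record: ProteinRecord, mode: str = "strict",
                      consensus: EgfConsensus = DEFAULT_EGF_CONSENSUS
                      ) -> list[DomainAnnotation]:
    """Greedy left-to-right, leftmost-longest, non-overlapping scan for
    tenascin-type EGF-like domains.  Strict hits are always a subset of
    relaxed hits."""
    segs = consensus.segments_for(mode)
    var_index = next(i for i, (_, a, b) in enumerate(segs) if a != b) \
        if any(a != b for _, a, b in segs) else 6
    seq = record.seq
    min_len, _ = consensus.span(mode)
    hits: list[DomainAnnotation] = []
    i = 0
    limit = len(seq) - min_len
    while i <= limit:
        # the pattern's second position is the first cysteine: cheap anchor
        if seq[i + 1] != "C" or seq[i] == "C":
            i += 1
            continue
        m = _match_at(seq, i, segs, var_index)
        if m is None:
            i += 1
            continue
        hits.append(DomainAnnotation(
            protein_id=record.id, kind=DomainKind.EGF_TN,
            start=i + 1, end=i + m, method=AnnotationMethod.BUILTIN))
        i += m
    return hits


# ------------------------------------------------------------ profile scan

@dataclass
class ReferenceProfile:
    """Exemplar-based detector for a domain class (length-bounded windows
    screened by alignment identity against packaged synthetic exemplars)."""

    kind: DomainKind
    seqs: list[str]
    min_identity: float = 35.0
    min_len: int = 80
    max_len: int = 110
    #: internal coarse-screen settings (edit-distance identity, sparse starts)
    step: int = 5
    prescreen_identity: float = 45.0

    def __post_init__(self):
        if not self.seqs:
            raise ValueError("reference profile needs at least one exemplar")


def default_fn3_profile() -> ReferenceProfile:
    return ReferenceProfile(kind=DomainKind.FN3, seqs=list(FN3_EXEMPLARS),
                            min_len=80, max_len=110)


def default_fred_profile() -> ReferenceProfile:
    return ReferenceProfile(kind=DomainKind.FRED, seqs=list(FRED_TEMPLATES.values()),
                            min_len=200, max_len=260)


def _edlib_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def detect_by_profile(record: ProteinRecord, profile: ReferenceProfile,
                      aligner=None, blocked: list[tuple[int, int]] | None = None,
                      overlap_tolerance: int = 10) -> list[DomainAnnotation]:
    """Sliding-window profile detection.

    Windows of each exemplar's length are screened at ``step`` spacing by
    edit-distance identity; local maxima are refined to single-residue
    precision and confirmed with the BLOSUM62 global aligner (identity over
    all alignment columns, the same convention as :mod:`tenascope.phylo`).
    Hits are reduced to an effectively non-overlapping set by descending
    identity, then left position; intervals in ``blocked`` are treated the
    same way.  Overlaps up to ``overlap_tolerance`` residues are allowed,
    since refined window boundaries jitter by a few residues around the true
    domain edges.
    """
    from .phylo import global_align  # local import, avoids cycle

    L = len(record.seq)
    candidates: list[tuple[float, int, int]] = []  # (identity, start0, length)
    for ex in profile.seqs:
        m = len(ex)
        if not (profile.min_len <= m <= profile.max_len) or m > L:
            continue
        starts = list(range(0, L - m + 1, profile.step))
        if starts[-1] != L - m:
            starts.append(L - m)
        coarse = [_edlib_identity(record.seq[s:s + m], ex) for s in starts]
        for j, (s, ident) in enumerate(zip(starts, coarse)):
            if ident < profile.prescreen_identity:
                continue
            left = coarse[j - 1] if j > 0 else -1.0
            right = coarse[j + 1] if j + 1 < len(coarse) else -1.0
            if ident < left or ident < right:
                continue  # not a local maximum
            # refine to single-residue precision around the coarse start
            best_s, best_i = s, ident
            for s2 in range(max(0, s - profile.step + 1),
                            min(L - m, s + profile.step - 1) + 1):
                i2 = _edlib_identity(record.seq[s2:s2 + m], ex)
                if i2 > best_i:
                    best_s, best_i = s2, i2
            aln = global_align(record.seq[best_s:best_s + m], ex)
            if aln.percent_identity >= profile.min_identity:
                candidates.append((aln.percent_identity, best_s, m))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, int]] = list(blocked or [])
    hits: list[DomainAnnotation] = []
    for ident, s0, m in candidates:
        iv = (s0 + 1, s0 + m)
        if any(min(e, iv[1]) - max(s, iv[0]) + 1 > overlap_tolerance
               for s, e in taken):
            continue
        taken.append(iv)
        hits.append((iv[0], iv[1], round(ident, 2)))
    # trim residual small overlaps so reported same-kind intervals are
    # strictly non-overlapping (scanner contract)
    hits.sort()
    trimmed: list[DomainAnnotation] = []
    last = 0
    for s, e, ident in hits:
        s = max(s, last + 1)
        for bs, be in (blocked or []):
            if s <= be and bs <= e:
                if bs > s:
                    e = min(e, bs - 1)
                else:
                    s = max(s, be + 1)
        if s > e:
            continue
        trimmed.append(DomainAnnotation(
            protein_id=record.id, kind=profile.kind, start=s, end=e,
            score=ident, method=AnnotationMethod.BUILTIN))
        last = e
    return trimmed


# ------------------------------------------------------------ signal peptide

def detect_signal_peptide(record: ProteinRecord) -> DomainAnnotation | None:
    """Fallback heuristic: a SIGNAL over residues 1..c is reported when the
    first 40 residues contain a run of >=8 consecutive hydrophobic residues
    (A,I,L,M,F,V,W,C) beginning at position <=12; c = end of the run + 5,
    capped at 40.  External SIGNAL annotations always override this."""
    prefix = record.seq[:40]
    for start in range(0, min(12, len(prefix))):
        run = 0
        while start + run < len(prefix) and prefix[start + run] in _SIGNAL_HYDROPHOBIC:
            run += 1
        if run >= 8:
            end = min(start + run + 5, 40, len(record.seq))
            return DomainAnnotation(protein_id=record.id, kind=DomainKind.SIGNAL,
                                    start=1, end=end,
                                    method=AnnotationMethod.BUILTIN)
    return None


# ------------------------------------------------------------ architecture

def build_architecture(record: ProteinRecord,
                       annotations: list[DomainAnnotation]) -> Architecture:
    """Sort annotations, resolve overlaps (EXTERNAL beats BUILTIN), compute
    grammar flags.  Overlapping same-kind BUILTIN annotations violate the
    scanner contract and raise."""
    for ann in annotations:
        if ann.protein_id != record.id:
            raise ValueError(f"annotation for {ann.protein_id} given to {record.id}")
        if ann.end > len(record.seq):
            raise ValueError(f"{record.id}: annotation beyond sequence end")

    builtin = [a for a in annotations if a.method == AnnotationMethod.BUILTIN]
    for kind in {a.kind for a in builtin}:
        same = sorted((a for a in builtin if a.kind == kind), key=lambda a: a.start)
        for prev, nxt in zip(same, same[1:]):
            if prev.overlaps(nxt):
                raise RuntimeError(
                    f"{record.id}: overlapping builtin {kind.value} annotations "
                    f"[{prev.start},{prev.end}] / [{nxt.start},{nxt.end}]")

    external = [a for a in annotations if a.method == AnnotationMethod.EXTERNAL]
    kept = list(external)
    for ann in builtin:
        if any(ann.overlaps(e) for e in external):
            continue  # defer to the external call
        kept.append(ann)
    kept.sort(key=lambda a: (a.start, a.end, a.kind.value))

    arch = Architecture(protein_id=record.id, seq_length=len(record.seq), domains=kept)
    arch.has_signal = any(d.kind == DomainKind.SIGNAL for d in kept)
    arch.has_coiled_coil = any(d.kind == DomainKind.COILED_COIL for d in kept)
    arch.n_egf = sum(d.kind == DomainKind.EGF_TN for d in kept)
    arch.n_fn3 = sum(d.kind == DomainKind.FN3 for d in kept)
    arch.has_terminal_fred = any(
        d.kind == DomainKind.FRED and len(record.seq) - d.end <= TERMINAL_FRED_WINDOW
        for d in kept)
    return arch


def classify_architecture(arch: Architecture, fragment: bool = False,
                          min_egf: int = 1, min_fn3: int = 1
                          ) -> tuple[bool, list[str]]:
    """Tenascin grammar: >=min_egf EGF-like + >=min_fn3 FN3 + carboxy-terminal
    FReD + signal peptide.  For fragments the signal clause is waived with
    reason code PARTIAL.  Returns (is_tenascin, reason_codes); reasons
    enumerate every failed clause."""
    reasons: list[str] = []
    if arch.n_egf < min_egf:
        reasons.append("NO_EGF")
    if arch.n_fn3 < min_fn3:
        reasons.append("NO_FN3")
    if not arch.has_terminal_fred:
        reasons.append("NO_FRED")
    if not arch.has_signal:
        if fragment:
            reasons.append("PARTIAL")
        else:
            reasons.append("NO_SIGNAL")
    failed = [r for r in reasons if r != "PARTIAL"]
    return (not failed, reasons)


def annotate_builtin(record: ProteinRecord,
                     egf_mode: str = "strict",
                     consensus: EgfConsensus = DEFAULT_EGF_CONSENSUS,
                     fn3_profile: ReferenceProfile | None = None,
                     fred_profile: ReferenceProfile | None = None
                     ) -> list[DomainAnnotation]:
    """Full builtin annotation pass: signal peptide, EGF scan, then FN3 and
    FReD profile detection with EGF intervals blocked (the EGF grammar is the
    higher-confidence signal, and tenascin domains never interleave)."""
    anns: list[DomainAnnotation] = []
    sig = detect_signal_peptide(record)
    if sig:
        anns.append(sig)
    egfs = scan_egf_tenascin(record, mode=egf_mode, consensus=consensus)
    anns.extend(egfs)
    blocked = [(e.start, e.end) for e in egfs]
    fn3 = detect_by_profile(record, fn3_profile or default_fn3_profile(),
                            blocked=blocked)
    anns.extend(fn3)
    blocked += [(d.start, d.end) for d in fn3]
    anns.extend(detect_by_profile(record, fred_profile or default_fred_profile(),
                                  blocked=blocked))
    return anns
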