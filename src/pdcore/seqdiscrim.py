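"""Sequence-level discrimination of E2 from E3BP.

E3BP is a catalytically inactive paralog of E2.  At the sequence level
the two are separated by (a) loss of the canonical transacetylase triad
histidine in the E3BP core-binding domain, and (b) a handful of short
motifs in the peripheral-subunit binding domain (PSBD) that are
conserved across both fungi and animals: a polar 'EKG' motif ending
PSBD helix 1 in E2; an arginine flanking a universally conserved
glycine; a hydrophobic motif after a conserved Asp with a solvent
exposed Leu ending helix 2 in E3BP; a 'GxI' helix-2 termination motif
in E3BP; and an Ascomycota-specific extension of alternating
hydrophobic residues.  Candidate E3BPs are then accepted when they show
an E2-homologous topology plus at least one of: an E3-specific PSBD, an
inactive catalytic domain, or an M3-like motif.

All motif coordinates are 1-based columns of a fixed alignment frame
(see :mod:`pdcore.synth` for the packaged synthetic reference frame);
mapping an unaligned sequence in requires aligning it to that frame
first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "HYDROPHOBIC",
    "AlignedSeqSet",
    "MotifProfile",
    "MotifRule",
    "default_rules",
    "column_stats",
    "triad_activity",
    "scan_motifs",
    "classify_e3bp",
    "motif_profile_from_group",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Residues accepted by the hydrophobic class symbol 'h'.
HYDROPHOBIC = frozenset("AVLIMFWY")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MAX_IC_BITS = float(np.log2(len(AMINO_ACIDS)))  # 4.3219...


@dataclass(frozen=True)
class AlignedSeqSet:
    """A multiple sequence alignment with per-record taxon-group labels."""

    ids: tuple[str, ...]
    groups: tuple[str, ...]      # e.g. animals, Pez, Sac, Asc, Zyg, Bas
    seqs: tuple[str, ...]        # aligned, upper-case, 20 residues + gap

    def __post_init__(self):
        if len(self.seqs) == 0:
            raise ValueError("alignment is empty")
        if not (len(self.ids) == len(self.groups) == len(self.seqs)):
            raise ValueError("ids, groups and seqs must have equal length")
        length = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(s)}, expected {length}"
                )
            bad = set(s) - set(AMINO_ACIDS) - {GAP}
            if bad:
                raise ValueError(f"record {sid!r} contains invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)

    def subset_by_group(self, group: str) -> "AlignedSeqSet":
        idx = [i for i, g in enumerate(self.groups) if g == group]
        if not idx:
            raise ValueError(f"no records with taxon group {group!r}")
        return AlignedSeqSet(
            ids=tuple(self.ids[i] for i in idx),
            groups=tuple(self.groups[i] for i in idx),
            seqs=tuple(self.seqs[i] for i in idx),
        )


@dataclass(frozen=True)
class MotifProfile:
    """Per-column residue frequencies and information content of an alignment.

    ``frequencies`` has one row per column over the 20 canonical residues
    (plus a final gap column when the gap policy treats gaps as a 21st
    symbol).  ``information`` is log2(alphabet) minus the Shannon column
    entropy, in bits — the height scale of a sequence logo.
    """

    span: tuple[int, int]                 # 1-based inclusive column interval
    frequencies: np.ndarray = field(repr=False)
    information: np.ndarray = field(repr=False)
    consensus: str = ""
    gap_fraction: np.ndarray = field(default=None, repr=False)
    high_gap_columns: tuple[int, ...] = ()   # 1-based columns >50% gap
    n_sequences: int = 0
    low_support: bool = False
    alphabet: str = AMINO_ACIDS

    def to_logo_dict(self) -> dict:
        """JSON-ready logo data: per-column frequencies and bit heights."""
        cols = list(range(self.span[0], self.span[1] + 1))
        return {
            "columns": cols,
            "alphabet": list(self.alphabet),
            "frequencies": [list(map(float, row)) for row in self.frequencies],
            "information_bits": [float(x) for x in self.information],
            "consensus": self.consensus,
            "high_gap_columns": list(self.high_gap_columns),
            "n_sequences": self.n_sequences,
        }


def _column_frequencies(column: str, gap_policy: str) -> tuple[np.ndarray, float]:
    counts = Counter(column)
    gap_frac = counts.get(GAP, 0) / len(column)
    if gap_policy == "exclude":
        total = len(column) - counts.get(GAP, 0)
        freqs = np.zeros(len(AMINO_ACIDS))
        if total > 0:
            for aa, c in counts.items():
                if aa != GAP:
                    freqs[_AA_INDEX[aa]] = c / total
    elif gap_policy == "symbol":
        freqs = np.zeros(len(AMINO_ACIDS) + 1)
        for aa, c in counts.items():
            idx = len(AMINO_ACIDS) if aa == GAP else _AA_INDEX[aa]
            freqs[idx] = c / len(column)
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}; accepted: 'exclude', 'symbol'")
    return freqs, gap_frac


def _consensus_char(freqs: np.ndarray, alphabet: str, threshold: float) -> str:
    top = float(freqs.max())
    if top == 0.0:
        return GAP
    winners = [alphabet[i] for i in np.flatnonzero(np.abs(freqs - top) < 1e-9)]
    if len(winners) == 1:
        ch = winners[0]
        return ch if top >= threshold else "x"
    if all(w in HYDROPHOBIC for w in winners):
        return "h"  # hydrophobic-class tie
    return "x"


def column_stats(
    msa: AlignedSeqSet,
    gap_policy: str = "exclude",
    high_gap_threshold: float = 0.5,
    consensus_threshold: float = 0.5,
) -> MotifProfile:
    """Residue frequencies, information content and consensus per column.

    Gap policy ``exclude`` renormalizes frequencies over residues only
    (the convention of residue-only sequence logos); ``symbol`` treats
    the gap as a 21st character.  Columns whose gap fraction exceeds
    *high_gap_threshold* are flagged.  Information content is
    ``log2(alphabet size) - H`` with H the Shannon entropy in bits, so an
    invariant column scores log2(20) = 4.32 bits and a uniform column 0.
    """
    alphabet = AMINO_ACIDS if gap_policy == "exclude" else AMINO_ACIDS + GAP
    length = msa.length
    freqs = np.zeros((length, len(alphabet)))
    gapf = np.zeros(length)
    for j in range(length):
        col = "".join(s[j] for s in msa.seqs)
        freqs[j], gapf[j] = _column_frequencies(col, gap_policy)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logp).sum(axis=1)
    totals = freqs.sum(axis=1)
    ic = np.where(totals > 0, np.log2(len(alphabet)) - entropy, 0.0)
    consensus = "".join(
        _consensus_char(freqs[j], alphabet, consensus_threshold) for j in range(length)
    )
    high_gap = tuple(int(j) + 1 for j in np.flatnonzero(gapf > high_gap_threshold))
    return MotifProfile(
        span=(1, length),
        frequencies=freqs,
        information=ic,
        consensus=consensus,
        gap_fraction=gapf,
        high_gap_columns=high_gap,
        n_sequences=len(msa),
        low_support=len(msa) < 2,
        alphabet=alphabet,
    )


def _covered_span(seq: str) -> tuple[int, int]:
    """1-based first/last non-gap column; (0, -1) for an all-gap record."""
    stripped = seq.strip(GAP)
    if not stripped:
        return (0, -1)
    first = len(seq) - len(seq.lstrip(GAP)) + 1
    last = len(seq.rstrip(GAP))
    return first, last


def triad_activity(seq: str, his_column: int) -> tuple[str, str]:
    """Catalytic state of a transacetylase-homologous sequence.

    A sequence is called ``active`` only if it holds His at the canonical
    triad position (*his_column*, 1-based alignment column); any other
    residue — or an internal gap — makes it ``inactive``, the signature
    by which E3BP is told apart from E2.  Columns outside the record's
    covered span (its leading/trailing gap region) are ``indeterminate``.

    Returns ``(state, note)``.
    """
    if not (1 <= his_column <= len(seq)):
        raise ValueError(
            f"his_column {his_column} outside alignment columns 1..{len(seq)}"
        )
    first, last = _covered_span(seq)
    if first == 0 or not (first <= his_column <= last):
        return "indeterminate", "triad column outside the record's covered span"
    ch = seq[his_column - 1]
    if ch == "H":
        return "active", "His present at triad column"
    if ch == GAP:
        return "inactive", "gap at triad column (internal deletion)"
    return "inactive", f"{ch} at triad column (His absent)"


@dataclass(frozen=True)
class MotifRule:
    """A positional motif over a fixed alignment-column frame.

    *patterns* are alternatives; a record matches the rule if any
    alternative matches.  Pattern symbols: a residue letter (exact), 'x'
    (any residue, gap excluded), 'h' (hydrophobic class).  *polarity*
    says which protein the motif marks ('E2', 'E3BP', or 'universal' for
    features shared by both, which carry no vote).  *groups* restricts
    the rule to specific taxon groups (None = all).
    """

    name: str
    span: tuple[int, int]            # 1-based inclusive
    patterns: tuple[str, ...]
    polarity: str                    # "E2" | "E3BP" | "universal"
    groups: tuple[str, ...] | None = None
    enabled: bool = True

    def __post_init__(self):
        lo, hi = self.span
        for p in self.patterns:
            if len(p) != hi - lo + 1:
                raise ValueError(f"rule {self.name!r}: pattern {p!r} does not fit span {self.span}")
        if self.polarity not in ("E2", "E3BP", "universal"):
            raise ValueError(f"rule {self.name!r}: invalid polarity {self.polarity!r}")


def default_rules() -> tuple[MotifRule, ...]:
    """The packaged PSBD discrimination rule set.

    Coordinates are columns of the packaged reference alignment frame.
    The helix-2 termination motif carries an alternate animal-frame span
    (54-56); the Ascomycota extension applies to Asc records only.
    """
    return (
        MotifRule("polar_EKG", (19, 21), ("EKG",), "E2"),
        # an Arg on either side of the conserved Gly at column 38
        MotifRule("flanking_Arg", (37, 39), ("RGx", "xGR"), "universal"),
        # conserved Asp at 43, universal solvent-exposed Leu at 45,
        # hydrophobic at 48 — the E3BP helix-2 hydrophobic motif
        MotifRule("Asp_Leu_hydrophobic", (43, 48), ("DxLhxh",), "E3BP"),
        MotifRule("GxI_termination", (49, 51), ("GxI",), "E3BP"),
        MotifRule("GxI_termination_animal", (54, 56), ("GxI",), "E3BP",
                  groups=("animals",), enabled=False),
        # Asc-specific extension: alternating hydrophobic coil
        MotifRule("Asc_extension", (68, 74), ("hxhxhxh",), "E3BP", groups=("Asc",)),
    )


def _match_pattern(window: str, pattern: str) -> tuple[bool, float]:
    """Match a window against one pattern; score = matched constrained positions."""
    constrained = matched = 0
    for ch, p in zip(window, pattern):
        if p == "x":
            if ch == GAP:
                return False, 0.0
            continue
        constrained += 1
        if p == "h":
            ok = ch in HYDROPHOBIC
        else:
            ok = ch == p
        if ok:
            matched += 1
    score = matched / constrained if constrained else 1.0
    return matched == constrained, score


@dataclass(frozen=True)
class MotifScan:
    """Per-rule match results and the aggregate E2/E3BP vote for one record."""

    results: dict[str, dict]   # rule name -> {matched, score, polarity, applied}
    vote: str                  # "E2" | "E3BP" | "unclassified"
    e2_votes: int
    e3bp_votes: int


def scan_motifs(
    seq: str,
    rules: tuple[MotifRule, ...] | None = None,
    group: str | None = None,
) -> MotifScan:
    """Scan an aligned record against the motif rule set and vote E2 vs E3BP.

    Each enabled rule applicable to the record's taxon *group* is matched
    within its span; the aggregate vote is the majority among matched
    polarity-carrying rules (universal rules characterize any PSBD and do
    not vote).  Ties — including no matches at all — yield
    ``unclassified``.
    """
    if rules is None:
        rules = default_rules()
    results: dict[str, dict] = {}
    e2 = e3bp = 0
    for rule in rules:
        lo, hi = rule.span
        if hi > len(seq):
            raise ValueError(
                f"rule {rule.name!r} span {rule.span} exceeds alignment length {len(seq)}"
            )
        applied = rule.enabled and (rule.groups is None or group in rule.groups)
        window = seq[lo - 1 : hi]
        matched, score = False, 0.0
        if applied:
            for pat in rule.patterns:
                ok, sc = _match_pattern(window, pat)
                score = max(score, sc)
                if ok:
                    matched = True
        results[rule.name] = {
            "matched": matched,
            "score": score,
            "polarity": rule.polarity,
            "applied": applied,
        }
        if matched:
            if rule.polarity == "E2":
                e2 += 1
            elif rule.polarity == "E3BP":
                e3bp += 1
    if e2 > e3bp:
        vote = "E2"
    elif e3bp > e2:
        vote = "E3BP"
    else:
        vote = "unclassified"
    return MotifScan(results=results, vote=vote, e2_votes=e2, e3bp_votes=e3bp)


#: Criterion keys for E3BP candidacy, in order:
#: (i) E2-homologous domain topology; (ii) E3-specific PSBD;
#: (iii) catalytically inactive CBD; (iv) M3-like motif present.
CRITERIA = ("topology", "e3_psbd", "inactive_cbd", "m3_motif")


@dataclass(frozen=True)
class ClassificationVerdict:
    verdict: str                  # "E3BP" | "E2-like" | "inconclusive"
    fired: tuple[str, ...]        # criteria that are true
    missing: tuple[str, ...]      # criteria that are unknown


def classify_e3bp(
    annotation: dict[str, bool | None],
    require_topology: bool = True,
    min_supporting: int = 1,
) -> ClassificationVerdict:
    """Apply the E3BP candidacy criteria to an annotated sequence.

    The default policy accepts a candidate as E3BP when its domain
    topology is E2-homologous (criterion i, gating) and at least
    *min_supporting* of the remaining criteria — E3-specific PSBD,
    inactive catalytic domain, M3-like motif — hold.  Different fungal
    groups satisfy different subsets (Basidiomycota: i + iv only), hence
    the or-combination.  A record is called E2-like only when topology
    holds but every supporting criterion is affirmatively false;
    anything resting on unknowns is inconclusive.  Each criterion flag
    may be True, False or None (unknown).
    """
    unknown_keys = [k for k in CRITERIA if annotation.get(k) is None]
    if len(unknown_keys) == len(CRITERIA):
        raise ValueError("all criteria are unknown; nothing to classify")
    bad = set(annotation) - set(CRITERIA)
    if bad:
        raise ValueError(f"unknown criteria {sorted(bad)}; accepted: {CRITERIA}")
    fired = tuple(k for k in CRITERIA if annotation.get(k) is True)
    supporting = [k for k in CRITERIA[1:] if annotation.get(k) is True]
    topology = annotation.get(CRITERIA[0])

    gate_ok = (topology is True) or (not require_topology and topology is None)
    if gate_ok and len(supporting) >= min_supporting:
        verdict = "E3BP"
    elif topology is True and all(annotation.get(k) is False for k in CRITERIA[1:]):
        verdict = "E2-like"
    else:
        verdict = "inconclusive"
    return ClassificationVerdict(verdict=verdict, fired=fired, missing=tuple(unknown_keys))


def motif_profile_from_group(
    msa: AlignedSeqSet,
    group: str,
    span: tuple[int, int],
    gap_policy: str = "exclude",
    consensus_threshold: float = 0.5,
) -> MotifProfile:
    """Logo profile of one taxon group restricted to an alignment span.

    Consensus characters use 'h' where tied modal residues are all
    hydrophobic (the Y/F-L/F-DGL-h style motifs) and 'x' below the
    *consensus_threshold* modal frequency.  Single-sequence subsets are
    returned but flagged ``low_support``.
    """
    lo, hi = span
    if not (1 <= lo <= hi <= msa.length):
        raise ValueError(f"span {span} outside alignment columns 1..{msa.length}")
    sub = msa.subset_by_group(group)
    prof = column_stats(sub, gap_policy=gap_policy, consensus_threshold=consensus_threshold)
    return replace(
        prof,
        span=(lo, hi),
        frequencies=prof.frequencies[lo - 1 : hi],
        information=prof.information[lo - 1 : hi],
        consensus=prof.consensus[lo - 1 : hi],
        gap_fraction=prof.gap_fraction[lo - 1 : hi],
        high_gap_columns=tuple(c for c in prof.high_gap_columns if lo <= c <= hi),
    )
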