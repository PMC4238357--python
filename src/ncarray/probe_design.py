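"""Multi-criterion PM oligo design and single-mismatch (MM) control construction.

Each probe region is scanned for the best antisense DNA oligo (18-30 nt,
preferred 25 nt) under a weighted combination of five sub-scores, each in
[0, 1] (1 = best):

``delta_tm``
    ``exp(-|Tm - tm_target| / 5)`` -- proximity of the DNA:RNA hybrid
    melting temperature to the chip-wide target (60 degC by default).
``position``
    ``1 - |center(oligo) - center(region)| / (len(region)/2)``, clipped to
    [0, 1] -- preference for the center of the selected region.
``complexity``
    Shannon entropy of the dinucleotide composition divided by its maximum
    (log2 16); homopolymers score 0.
``folding``
    ``1 - min(1, longest self-complementary stem / 10)`` -- penalizes
    hairpin-prone oligos.
``crosshyb``
    ``1 - longest contiguous off-target match / oligo length``, where
    off-targets are all background transcripts except the probe's own source
    contig, found by a 12-mer seeded scan.

Sub-scores are combined as a weighted mean with the weights renormalized to
sum to 1 (the platform's published emphasis -- 24.2% cross-hybridization,
32.3% delta Tm, 6.1% folding, 11.3% position, 16.1% complexity -- sums to
0.900 as stated).

The MM control is the PM sequence with a single substitution at position 13
(1-based from the probe 5' end).  The substituted base must actually
mismatch the opposing RNA base and must not form a G-T/G-U juxtaposition
with it (no G opposite U, no T opposite G): wobble pairs retain duplex
stability and would defeat the purpose of the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from ._seq import DNA_COMPLEMENT_OF_RNA, revcomp_dna, to_dna, to_rna, validate_alphabet
from .region_selection import CoverageContig, ProbeRegion

__all__ = [
    "DesignWeights",
    "DesignParams",
    "ProbePair",
    "BackgroundIndex",
    "melting_temperature",
    "sub_scores",
    "combined_score",
    "design_pm",
    "design_mm",
    "design_probes",
    "make_spike_and_snrna_controls",
    "write_probe_fasta",
    "write_design_report",
]

SCORE_NAMES = ("crosshyb", "delta_tm", "folding", "position", "complexity")


@dataclass
class DesignWeights:
    """Relative emphasis of the five design sub-scores.

    The stored weights need not sum to 1 (the platform defaults sum to
    0.900); scores are always combined with the weights renormalized.
    """

    w_crosshyb: float = 0.242
    w_delta_tm: float = 0.323
    w_folding: float = 0.061
    w_position: float = 0.113
    w_complexity: float = 0.161

    def as_dict(self) -> dict[str, float]:
        return {
            "crosshyb": self.w_crosshyb,
            "delta_tm": self.w_delta_tm,
            "folding": self.w_folding,
            "position": self.w_position,
            "complexity": self.w_complexity,
        }

    def normalized(self) -> dict[str, float]:
        raw = self.as_dict()
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("at least one design weight must be positive")
        return {k: v / total for k, v in raw.items()}


@dataclass
class DesignParams:
    """Oligo design constraints: Tm target, length window, MM position."""

    tm_target: float = 60.0
    oligo_len_pref: int = 25
    oligo_len_min: int = 18
    oligo_len_max: int = 30
    mm_position: int = 13
    na_molar: float = 1.0  # monovalent cation conc. for the salt correction

    def __post_init__(self) -> None:
        if not (self.oligo_len_min <= self.oligo_len_pref <= self.oligo_len_max):
            raise ValueError("require len_min <= len_pref <= len_max")
        if self.mm_position > self.oligo_len_min:
            raise ValueError("mm_position must fit inside the shortest oligo")


@dataclass
class ProbePair:
    """A PM oligo with its optional MM partner and design diagnostics."""

    probe_id: str
    pm_sequence: str
    mm_sequence: Optional[str]
    target_contig: str
    target_offset: int
    target_length: int
    sub_scores: dict[str, float] = field(default_factory=dict)
    combined_score: float = 0.0
    tm: float = float("nan")
    role: str = "signal"  # signal | control_region | spike_in | snRNA_control
    biotype: str = "unknown"

    @property
    def has_mm(self) -> bool:
        return self.mm_sequence is not None


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def melting_temperature(
    dna_probe: str,
    rna_target: str | None = None,
    *,
    na_molar: float = 1.0,
    total_strand_nM: float = 250.0,
) -> float:
    """Nearest-neighbor Tm (degC) of a DNA probe bound to its RNA target.

    Uses the Sugimoto 1995 RNA/DNA hybrid parameter set (1 M Na+ reference)
    with an entropy-based salt correction to ``na_molar``.  ``rna_target``
    defaults to the exact complement of the probe; when given it must be
    fully complementary (mismatched duplex Tm is outside this model).
    """
    validate_alphabet(dna_probe, context="dna_probe")
    probe = to_dna(dna_probe)
    if len(probe) < 8:
        raise ValueError("duplex too short for the nearest-neighbor model")
    if rna_target is None:
        rna = to_rna(revcomp_dna(probe))
    else:
        validate_alphabet(rna_target, context="rna_target")
        rna = to_rna(rna_target)
        if to_dna(revcomp_dna(probe)) != to_dna(rna):
            raise ValueError("rna_target is not the complement of dna_probe")
    # Bio's R_DNA_NN1 expects the RNA strand 5'->3' as `seq`; equal strand
    # concentrations give C_T/4 in the denominator; saltcorr=5 is the
    # entropy correction 0.368*(N-1)*ln[Na+], zero at the 1 M reference.
    return float(
        _mt.Tm_NN(
            rna,
            nn_table=_mt.R_DNA_NN1,
            Na=na_molar * 1000.0,
            saltcorr=5,
            dnac1=total_strand_nM / 2.0,
            dnac2=total_strand_nM / 2.0,
        )
    )


# ---------------------------------------------------------------------------
# Background index for cross-hybridization screening
# ---------------------------------------------------------------------------

class BackgroundIndex:
    """k-mer index over background transcripts for off-target matching.

    Sequences are indexed in the RNA-sense (target) orientation; queries are
    target subsequences, so a hit is a stretch another transcript shares with
    the probe's intended target, i.e. a cross-hybridization risk.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None, k: int = 12):
        self.k = k
        self._seqs: dict[str, str] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in (sequences or {}).items():
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        s = to_dna(seq)
        self._seqs[name] = s
        for i in range(len(s) - self.k + 1):
            self._index.setdefault(s[i : i + self.k], []).append((name, i))

    def __len__(self) -> int:
        return len(self._seqs)

    def longest_match(self, query: str, exclude: str | None = None) -> int:
        """Length of the longest contiguous match of ``query`` against any
        indexed sequence except ``exclude``.  Matches shorter than the seed
        size k are not detected and count as 0."""
        q = to_dna(query)
        best = 0
        for i in range(len(q) - self.k + 1):
            for name, j in self._index.get(q[i : i + self.k], ()):
                if name == exclude:
                    continue
                s = self._seqs[name]
                left_i, left_j = i, j
                while left_i > 0 and left_j > 0 and q[left_i - 1] == s[left_j - 1]:
                    left_i -= 1
                    left_j -= 1
                right_i, right_j = i + self.k, j + self.k
                while right_i < len(q) and right_j < len(s) and q[right_i] == s[right_j]:
                    right_i += 1
                    right_j += 1
                best = max(best, right_i - left_i)
        return best


# ---------------------------------------------------------------------------
# Sub-scores
# ---------------------------------------------------------------------------

def _dinucleotide_entropy(seq: str) -> float:
    s = to_dna(seq)
    if len(s) < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(len(s) - 1):
        counts[s[i : i + 2]] = counts.get(s[i : i + 2], 0) + 1
    total = sum(counts.values())
    probs = np.array(list(counts.values())) / total
    return float(-(probs * np.log2(probs)).sum())


def _max_self_complementary_stem(seq: str) -> int:
    """Longest common substring between the oligo and its own reverse
    complement = longest perfect hairpin stem it can form with itself."""
    s = to_dna(seq)
    r = revcomp_dna(s)
    n = len(s)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if s[i - 1] == r[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def sub_scores(
    oligo_offset: int,
    oligo_length: int,
    region: ProbeRegion,
    contig: CoverageContig,
    params: DesignParams | None = None,
    background: BackgroundIndex | None = None,
) -> dict[str, float]:
    """The five design sub-scores of one candidate oligo (all in [0, 1]).

    ``oligo_offset`` is transcript-sense within the contig.
    """
    params = params or DesignParams()
    target = to_dna(contig.sequence[oligo_offset : oligo_offset + oligo_length])
    probe = revcomp_dna(target)

    tm = melting_temperature(probe, na_molar=params.na_molar)
    delta_tm = float(np.exp(-abs(tm - params.tm_target) / 5.0))

    oligo_center = oligo_offset + oligo_length / 2.0
    region_center = region.offset + region.length / 2.0
    position = 1.0 - abs(oligo_center - region_center) / (region.length / 2.0)
    position = float(np.clip(position, 0.0, 1.0))

    complexity = _dinucleotide_entropy(probe) / np.log2(16.0)

    folding = 1.0 - min(1.0, _max_self_complementary_stem(probe) / 10.0)

    if background is not None and len(background):
        match = background.longest_match(target, exclude=contig.contig_id)
        crosshyb = 1.0 - match / oligo_length
    else:
        crosshyb = 1.0

    return {
        "crosshyb": float(crosshyb),
        "delta_tm": delta_tm,
        "folding": float(folding),
        "position": position,
        "complexity": float(complexity),
    }


def combined_score(scores: Mapping[str, float], weights: DesignWeights | None = None) -> float:
    """Weighted mean of the sub-scores with weights renormalized to sum 1."""
    w = (weights or DesignWeights()).normalized()
    return float(sum(w[name] * scores[name] for name in SCORE_NAMES))


# ---------------------------------------------------------------------------
# PM / MM design
# ---------------------------------------------------------------------------

def design_pm(
    region: ProbeRegion,
    contig: CoverageContig,
    params: DesignParams | None = None,
    weights: DesignWeights | None = None,
    background: BackgroundIndex | None = None,
    probe_id: str | None = None,
) -> ProbePair:
    """Exhaustively score every candidate oligo within the region and return
    the best as a PM-only :class:`ProbePair`.

    Ties break toward the preferred length (25 nt), then leftmost.  The PM
    sequence is the DNA reverse complement of the targeted RNA subsequence,
    written 5'->3'.
    """
    params = params or DesignParams()
    weights = weights or DesignWeights()
    if region.length < params.oligo_len_min:
        raise ValueError(
            f"region {region.contig_id}:{region.offset} shorter than the minimum "
            f"oligo length ({region.length} < {params.oligo_len_min})"
        )
    best = None
    max_len = min(params.oligo_len_max, region.length)
    for length in range(params.oligo_len_min, max_len + 1):
        for off in range(region.offset, region.offset + region.length - length + 1):
            scores = sub_scores(off, length, region, contig, params, background)
            score = combined_score(scores, weights)
            key = (-score, abs(length - params.oligo_len_pref), off)
            if best is None or key < best[0]:
                best = (key, off, length, scores, score)
    _, off, length, scores, score = best
    target = to_dna(contig.sequence[off : off + length])
    return ProbePair(
        probe_id=probe_id or f"{contig.contig_id}_{region.offset}",
        pm_sequence=revcomp_dna(target),
        mm_sequence=None,
        target_contig=contig.contig_id,
        target_offset=off,
        target_length=length,
        sub_scores=scores,
        combined_score=score,
        tm=melting_temperature(revcomp_dna(target), na_molar=params.na_molar),
        role="signal" if region.kind == "signal" else "control_region",
        biotype=contig.biotype,
    )


#: Preferred substitution per PM base: the A<->C / G<->T transversion partner.
_MM_PRIORITY = {"A": "C", "C": "A", "G": "T", "T": "G"}


def design_mm(pm_sequence: str, rna_target: str, params: DesignParams | None = None) -> str:
    """Construct the MM control: one substitution at ``mm_position`` (1-based
    from the probe 5' end).

    The substituted base (i) must not be complementary to the opposing RNA
    base (it must be a true mismatch), (ii) must not be G when the opposing
    base is U, and (iii) must not be T when the opposing base is G -- rules
    (ii)/(iii) exclude stabilizing G-U/G-T wobble juxtapositions.  Among the
    allowed bases the transversion partner of the PM base is preferred,
    falling back to alphabetical order.
    """
    params = params or DesignParams()
    pm = to_dna(pm_sequence)
    rna = to_rna(rna_target)
    pos = params.mm_position
    if len(pm) < pos:
        raise ValueError(f"PM probe shorter than mm_position ({len(pm)} < {pos})")
    if len(rna) != len(pm):
        raise ValueError("rna_target length must equal PM probe length")
    # probe position i (1-based from its 5' end) pairs with the target base
    # at index len - i from the target 5' end (antiparallel duplex)
    opposing = rna[len(pm) - pos]
    pm_base = pm[pos - 1]
    allowed = [
        b
        for b in "ACGT"
        if b != pm_base
        and b != DNA_COMPLEMENT_OF_RNA[opposing]
        and not (b == "G" and opposing == "U")
        and not (b == "T" and opposing == "G")
    ]
    assert allowed, "no admissible substitution -- impossible for a 4-letter alphabet"
    preferred = _MM_PRIORITY[pm_base]
    mm_base = preferred if preferred in allowed else allowed[0]
    return pm[: pos - 1] + mm_base + pm[pos:]


def design_probes(
    contigs: Iterable[CoverageContig],
    selection_config=None,
    params: DesignParams | None = None,
    weights: DesignWeights | None = None,
    background: BackgroundIndex | None = None,
) -> tuple[list[ProbeRegion], list[ProbePair]]:
    """Full design path: regions -> PM probes (+MM for signal regions).

    Control-region probes are spotted without an MM partner.  When no
    explicit background index is given, the contig set itself serves as the
    cross-hybridization background (each probe's own contig excluded).
    """
    from .region_selection import SelectionConfig, select_control_region, select_signal_regions

    contigs = list(contigs)
    selection_config = selection_config or SelectionConfig()
    params = params or DesignParams()
    if background is None:
        background = BackgroundIndex({c.contig_id: c.sequence for c in contigs})
    regions: list[ProbeRegion] = []
    probes: list[ProbePair] = []
    for contig in contigs:
        signal = select_signal_regions(contig, selection_config)
        control = select_control_region(contig, selection_config, signal)
        for i, reg in enumerate(signal, 1):
            probe = design_pm(reg, contig, params, weights, background,
                              probe_id=f"{contig.contig_id}_r{i}")
            target = to_dna(
                contig.sequence[probe.target_offset : probe.target_offset + probe.target_length]
            )
            probe.mm_sequence = design_mm(probe.pm_sequence, target, params)
            probes.append(probe)
        if control is not None:
            probes.append(
                design_pm(control, contig, params, weights, background,
                          probe_id=f"{contig.contig_id}_ctrl")
            )
        regions.extend(signal + ([control] if control else []))
    return regions, probes


# ---------------------------------------------------------------------------
# Spike-in and snRNA control probes
# ---------------------------------------------------------------------------

def _synthetic_snrna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


#: Synthetic stand-ins for the U2/U6 snRNA sequences, generated from a fixed
#: seed at realistic lengths (U2 ~191 nt, U6 ~107 nt).  Real snRNA records
#: are not bundled; pass your own sequences for a production chip.
SYNTHETIC_U2 = _synthetic_snrna(np.random.default_rng(20260901), 191)
SYNTHETIC_U6 = _synthetic_snrna(np.random.default_rng(20260902), 107)


def make_spike_and_snrna_controls(
    seed: int,
    u2_sequence: str = SYNTHETIC_U2,
    u6_sequence: str = SYNTHETIC_U6,
    n_spike: int = 8,
    n_snrna_each: int = 20,
    params: DesignParams | None = None,
) -> list[ProbePair]:
    """Eight seeded random spike-in probes plus 40 U2/U6 snRNA probes.

    Spike-ins are 25-mers with 40-60% GC and no self-complementary stem of
    6 nt or more.  snRNA probes tile the supplied U2/U6 sequences at evenly
    spaced offsets (20 probes each by default).  None carries an MM partner.
    """
    params = params or DesignParams()
    rng = np.random.default_rng(seed)
    probes: list[ProbePair] = []
    for i in range(1, n_spike + 1):
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=25))
            gc = (seq.count("G") + seq.count("C")) / 25.0
            if 0.40 <= gc <= 0.60 and _max_self_complementary_stem(seq) < 6:
                break
        probes.append(
            ProbePair(
                probe_id=f"spike_{i}",
                pm_sequence=seq,
                mm_sequence=None,
                target_contig="spike_in",
                target_offset=0,
                target_length=25,
                tm=melting_temperature(seq, na_molar=params.na_molar),
                role="spike_in",
                biotype="spike_in",
            )
        )
    for name, seq in (("U2", u2_sequence), ("U6", u6_sequence)):
        target_seq = to_dna(seq)
        span = len(target_seq) - 25
        if span < n_snrna_each - 1:
            raise ValueError(
                f"{name} sequence too short to tile {n_snrna_each} distinct 25-mer probes"
            )
        for i in range(n_snrna_each):
            off = round(i * span / (n_snrna_each - 1))
            target = target_seq[off : off + 25]
            probes.append(
                ProbePair(
                    probe_id=f"{name}_{i + 1:02d}",
                    pm_sequence=revcomp_dna(target),
                    mm_sequence=None,
                    target_contig=name,
                    target_offset=off,
                    target_length=25,
                    tm=melting_temperature(revcomp_dna(target), na_molar=params.na_molar),
                    role="snRNA_control",
                    biotype="snRNA",
                )
            )
    return probes


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_probe_fasta(probes: Iterable[ProbePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}_PM\n{p.pm_sequence}\n")
            if p.mm_sequence is not None:
                fh.write(f">{p.probe_id}_MM\n{p.mm_sequence}\n")


def write_design_report(probes: Iterable[ProbePair], path: str | Path) -> None:
    cols = "\t".join(SCORE_NAMES)
    with open(path, "w") as fh:
        fh.write(
            "probe_id\trole\tbiotype\ttarget_contig\ttarget_offset\ttarget_length\t"
            f"pm_sequence\tmm_sequence\ttm\tcombined_score\t{cols}\n"
        )
        for p in probes:
            scores = "\t".join(f"{p.sub_scores.get(n, float('nan')):.4f}" for n in SCORE_NAMES)
            fh.write(
                f"{p.probe_id}\t{p.role}\t{p.biotype}\t{p.target_contig}\t{p.target_offset}\t"
                f"{p.target_length}\t{p.pm_sequence}\t{p.mm_sequence or ''}\t{p.tm:.2f}\t"
                f"{p.combined_score:.4f}\t{scores}\n"
            )
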