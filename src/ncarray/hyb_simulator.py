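"""Generative model for two-color dye-swap hybridizations with known truth.

The simulator produces GPR-like scan tables for a dye-swap experiment --
``n_pairs`` biological replicates, each hybridized twice with the Cy3/Cy5
condition assignment reversed -- over any :class:`~ncarray.array_layout.ArrayDesign`.

Per-spot generative model (all logs base 2 unless noted):

* specific signal ``S = 2**(mu_g + x_c * beta_g + biological noise)`` where
  ``x_c`` is 1 for the case condition, 0 for control; biological noise is
  drawn independently per gene, array and condition (each hybridization uses
  its own aliquot/labeling of the sample);
* MM spots see ``kappa * S`` (cross-hybridization fraction, < 1 so PM
  exceeds MM whenever there is specific signal);
* channel foreground
  ``F = tip_b(a) * dye_factor * (S + nu) * exp(eps) + B`` with
  ``tip_b(a) = 2**(+-g_b(a)/2)`` a smooth per-block quadratic curvature in
  the spot's mean log-intensity (sign + for the Cy5 channel, - for Cy3),
  ``dye_factor = 2**(+-delta_g/2)`` the gene-wise dye bias (same sign
  convention), ``nu`` a nonspecific floor, ``eps ~ N(0, sigma_eps^2)``
  multiplicative scanner/labeling noise, and ``B`` the local background
  drawn around level ``b``;
* the reported background column equals the drawn ``B``, so net intensity
  recovers the pre-background product exactly in the noise-free limit.

The block curvature and the dye bias are what the print-tip loess and the
dye-swap averaging of the analysis pipeline exist to remove; setting every
noise parameter to zero yields the exact closed form
``F - B = 2**(mu + x*beta)`` on PM spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .array_layout import ArrayDesign
from .probe_design import ProbePair, make_spike_and_snrna_controls
from .region_selection import CoverageContig

__all__ = [
    "TruthModel",
    "TwoColorScan",
    "simulate_experiment",
    "simulate_design_inputs",
    "synthetic_probe_panel",
    "write_scan",
    "read_scan",
    "write_experiment_sheet",
    "read_experiment_sheet",
]

GPR_COLUMNS = [
    "Block",
    "Row",
    "Column",
    "ID",
    "Name",
    "F635 Median",
    "B635 Median",
    "F532 Median",
    "B532 Median",
]


@dataclass
class TruthModel:
    """Ground-truth expression model for one simulated experiment.

    Scalar fields are the study conditions; the per-candidate arrays
    (``mu``, ``beta``, ``delta``) and per-block curvature coefficients are
    realized by :meth:`generate`.
    """

    candidate_ids: list[str] = field(default_factory=list)
    mu: np.ndarray = field(default_factory=lambda: np.array([]))  # baseline log2 expression
    beta: np.ndarray = field(default_factory=lambda: np.array([]))  # log2 fold change, 0 = null
    delta: np.ndarray = field(default_factory=lambda: np.array([]))  # gene-wise dye bias
    tip_coefs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # per block: c0,c1,c2
    fraction_de: float = 0.1
    effect_size: float = 1.0
    mu_range: tuple[float, float] = (6.0, 12.0)
    sigma_bio: float = 0.1  # log2, per gene x array x condition
    sigma_dye: float = 0.05  # log2 sd of gene-wise dye bias
    sigma_eps: float = 0.12  # natural-log multiplicative intensity noise (~12% CV)
    background: float = 100.0
    sigma_background: float = 10.0
    kappa: float = 0.2  # MM cross-hybridization fraction, < 1
    nu: float = 2.0  # nonspecific signal floor (intensity units)
    tip_sd: tuple[float, float, float] = (0.10, 0.05, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa < 1.0):
            raise ValueError("kappa must lie in [0, 1)")
        if min(self.sigma_bio, self.sigma_dye, self.sigma_eps, self.sigma_background) < 0:
            raise ValueError("noise scales must be non-negative")

    @classmethod
    def generate(
        cls, candidate_ids: Sequence[str], n_blocks: int, seed: int = 0, **overrides
    ) -> "TruthModel":
        """Draw per-candidate truth and per-block curvature from ``seed``."""
        truth = cls(seed=seed, **overrides)
        rng = np.random.default_rng(seed)
        n = len(candidate_ids)
        mu = rng.uniform(*truth.mu_range, size=n)
        beta = np.zeros(n)
        n_de = int(round(truth.fraction_de * n))
        de_idx = rng.choice(n, size=n_de, replace=False)
        beta[de_idx] = truth.effect_size * rng.choice([-1.0, 1.0], size=n_de)
        delta = rng.normal(0.0, truth.sigma_dye, size=n)
        c = np.column_stack(
            [rng.normal(0.0, sd, size=n_blocks) for sd in truth.tip_sd]
        )
        truth.candidate_ids = list(candidate_ids)
        truth.mu, truth.beta, truth.delta, truth.tip_coefs = mu, beta, delta, c
        return truth

    def noise_free(self) -> "TruthModel":
        """A copy with every stochastic term switched off (closed-form limit)."""
        return replace(
            self,
            sigma_bio=0.0,
            sigma_dye=0.0,
            sigma_eps=0.0,
            sigma_background=0.0,
            tip_coefs=np.zeros_like(self.tip_coefs),
            delta=np.zeros_like(self.delta),
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate_id": self.candidate_ids,
                "mu": self.mu,
                "log2fc": self.beta,
                "is_de": self.beta != 0.0,
            }
        )


@dataclass
class TwoColorScan:
    """One array's per-spot two-channel intensities plus dye assignment.

    ``spots`` carries the GPR-like columns; ``dye_assignment`` maps channel
    ('ch635'/'ch532') to condition name.
    """

    array_id: str
    spots: pd.DataFrame
    dye_assignment: dict[str, str]


def _design_frame(design: ArrayDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Block": [s.block for s in design.spots],
            "Row": [s.row for s in design.spots],
            "Column": [s.col for s in design.spots],
            "ID": [
                (s.probe_id if s.pair_role == "single" else f"{s.probe_id}.{s.pair_role}")
                + f".{s.replicate_index}"
                for s in design.spots
            ],
            "Name": [s.probe_id for s in design.spots],
            "pair_role": [s.pair_role for s in design.spots],
        }
    )


def simulate_experiment(
    design: ArrayDesign,
    truth: TruthModel,
    n_pairs: int = 3,
    conditions: tuple[str, str] = ("case", "control"),
) -> tuple[list[TwoColorScan], pd.DataFrame, pd.DataFrame]:
    """Simulate ``2 * n_pairs`` scans (a dye-swap pair per biological replicate).

    Returns ``(scans, experiment_sheet, truth_table)``.  The experiment
    sheet has columns array_id, ch635_condition, ch532_condition, pair_id,
    biological_replicate.  Probes absent from the truth's candidate list
    (spike-ins, snRNA controls) are simulated at a fixed baseline with zero
    fold change and zero dye bias.
    """
    case, control = conditions
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    frame = _design_frame(design)

    idx_of = {cid: i for i, cid in enumerate(truth.candidate_ids)}
    gene_idx = np.array([idx_of.get(name, -1) for name in frame["Name"]])
    known = gene_idx >= 0
    mu = np.where(known, truth.mu[gene_idx], 10.0)
    beta = np.where(known, truth.beta[gene_idx], 0.0)
    delta = np.where(known, truth.delta[gene_idx], 0.0)
    is_mm = (frame["pair_role"] == "MM").to_numpy()
    block0 = frame["Block"].to_numpy() - 1
    c0, c1, c2 = (truth.tip_coefs[block0, i] for i in range(3))
    a_centered = (mu - np.mean(truth.mu_range)) / 3.0  # scaled log-intensity coordinate
    tip_m = c0 + c1 * a_centered + c2 * a_centered**2  # block trend on the M scale

    # per-gene x array x condition biological noise keyed by candidate index
    n_genes = len(truth.candidate_ids)
    scans: list[TwoColorScan] = []
    sheet_rows = []
    for pair in range(1, n_pairs + 1):
        for swap in (0, 1):
            array_id = f"array_{pair}{'ab'[swap]}"
            ch635_cond, ch532_cond = (case, control) if swap == 0 else (control, case)
            bio = rng.normal(0.0, truth.sigma_bio, size=(n_genes, 2))  # cols: case, control
            spot_cols = {}
            for channel, cond in (("635", ch635_cond), ("532", ch532_cond)):
                x = 1.0 if cond == case else 0.0
                bio_term = np.where(
                    known, bio[gene_idx, 0 if cond == case else 1], 0.0
                )
                log2_s = mu + x * beta + bio_term
                s = np.exp2(log2_s)
                s = np.where(is_mm, truth.kappa * s, s)
                dye_sign = 1.0 if channel == "635" else -1.0
                factor = np.exp2(dye_sign * (tip_m + delta) / 2.0)
                eps = rng.normal(0.0, truth.sigma_eps, size=len(frame))
                b = np.maximum(
                    rng.normal(truth.background, truth.sigma_background, size=len(frame)), 0.0
                )
                spot_cols[f"F{channel} Median"] = factor * (s + truth.nu) * np.exp(eps) + b
                spot_cols[f"B{channel} Median"] = b
            spots = frame.drop(columns="pair_role").assign(**spot_cols)[GPR_COLUMNS]
            scans.append(
                TwoColorScan(array_id, spots, {"ch635": ch635_cond, "ch532": ch532_cond})
            )
            sheet_rows.append(
                {
                    "array_id": array_id,
                    "ch635_condition": ch635_cond,
                    "ch532_condition": ch532_cond,
                    "pair_id": pair,
                    "biological_replicate": pair,
                }
            )
    return scans, pd.DataFrame(sheet_rows), truth.truth_table()


# ---------------------------------------------------------------------------
# Synthetic probe panel (simulation without running the design path)
# ---------------------------------------------------------------------------

def synthetic_probe_panel(
    n_candidates: int, seed: int = 0, n_control_regions: int = 0
) -> list[ProbePair]:
    """A chip-like probe panel: ``n_candidates`` PM/MM signal pairs plus the
    standard 48 controls (8 spike-ins + 40 snRNA probes) and optional
    MM-less control-region probes.  Sequences are random 25-mers; the panel
    exists to exercise layout/simulation/analysis at scale."""
    rng = np.random.default_rng(seed)
    probes = []
    for i in range(1, n_candidates + 1):
        pm = "".join(rng.choice(list("ACGT"), size=25))
        mm = pm[:12] + {"A": "C", "C": "A", "G": "T", "T": "G"}[pm[12]] + pm[13:]
        probes.append(
            ProbePair(
                probe_id=f"cand_{i:05d}",
                pm_sequence=pm,
                mm_sequence=mm,
                target_contig=f"cand_{i:05d}",
                target_offset=0,
                target_length=25,
                role="signal",
            )
        )
    for i in range(1, n_control_regions + 1):
        probes.append(
            ProbePair(
                probe_id=f"ctrl_{i:05d}",
                pm_sequence="".join(rng.choice(list("ACGT"), size=25)),
                mm_sequence=None,
                target_contig=f"ctrl_{i:05d}",
                target_offset=0,
                target_length=25,
                role="control_region",
            )
        )
    probes.extend(make_spike_and_snrna_controls(seed=seed + 1))
    return probes


# ---------------------------------------------------------------------------
# Design-path fixture generator
# ---------------------------------------------------------------------------

def simulate_design_inputs(
    n_contigs: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[CoverageContig]:
    """Generate coverage contigs with plateau+peak profiles and optionally
    write them as BED6 + bedGraph + FASTA fixtures.

    Contig lengths span 20-400 nt (log-uniform).  Coverage is a low plateau
    with, on longer contigs, a high-coverage peak confined to one 30-nt grid
    window -- the profile of a processed small RNA excised from a longer
    precursor, which region selection should recover.  Biotype tags follow
    the platform's approximate composition.  Deterministic by ``seed``.
    """
    rng = np.random.default_rng(seed)
    biotypes = ["snoRNA", "miRNA", "tRF", "unknown"]
    probs = [0.11, 0.13, 0.06, 0.70]
    contigs = []
    pos = 1000
    for i in range(1, n_contigs + 1):
        length = int(round(np.exp(rng.uniform(np.log(20), np.log(400)))))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        base = rng.integers(1, 6)
        coverage = np.full(length, float(base))
        if length >= 60 and rng.random() < 0.7:
            # peak inside one 30-nt grid window
            n_windows = length // 30
            w = int(rng.integers(0, n_windows))
            peak = base + rng.integers(10, 60)
            coverage[w * 30 : w * 30 + 30] = float(peak)
        coverage += rng.poisson(0.5, size=length)
        read_count = int(round(coverage.sum() / 25.0))
        if rng.random() < 0.1:  # some under-supported loci to exercise filtering
            read_count = int(rng.integers(0, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        contigs.append(
            CoverageContig(
                contig_id=f"contig_{i:04d}",
                chrom="chrSim",
                start=pos,
                end=pos + length,
                strand=strand,
                sequence=seq,
                coverage=coverage,
                read_count=read_count,
                biotype=str(rng.choice(biotypes, p=probs)),
            )
        )
        pos += length + 100
    if out_dir is not None:
        _write_design_fixtures(contigs, Path(out_dir))
    return contigs


def _write_design_fixtures(contigs: Sequence[CoverageContig], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "contigs.bed", "w") as bed, open(
        out_dir / "coverage.bedgraph", "w"
    ) as bg, open(out_dir / "contigs.fasta", "w") as fa:
        for c in contigs:
            bed.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.contig_id}|{c.biotype}\t{c.read_count}\t{c.strand}\n"
            )
            # genome-strand sequence & coverage (read_contigs flips minus strands back)
            seq = c.sequence
            cov = c.coverage
            if c.strand == "-":
                from ._seq import revcomp_dna

                seq = revcomp_dna(seq)
                cov = cov[::-1]
            fa.write(f">{c.contig_id}\n{seq}\n")
            run_start = 0
            for i in range(1, len(cov) + 1):
                if i == len(cov) or cov[i] != cov[run_start]:
                    if cov[run_start] != 0:
                        bg.write(
                            f"{c.chrom}\t{c.start + run_start}\t{c.start + i}\t{cov[run_start]:g}\n"
                        )
                    run_start = i


# ---------------------------------------------------------------------------
# Scan / sheet I/O (GPR-like dialect)
# ---------------------------------------------------------------------------

def write_scan(scan: TwoColorScan, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# array_id={scan.array_id} "
            f"ch635={scan.dye_assignment['ch635']} ch532={scan.dye_assignment['ch532']}\n"
        )
        scan.spots.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_scan(path: str | Path) -> TwoColorScan:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing scan header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        spots = pd.read_csv(fh, sep="\t")
    missing = set(GPR_COLUMNS) - set(spots.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TwoColorScan(meta["array_id"], spots, {"ch635": meta["ch635"], "ch532": meta["ch532"]})


def write_experiment_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_experiment_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
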