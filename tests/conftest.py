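import numpy as np
import pytest

from ncarray.array_layout import layout_array
from ncarray.hyb_simulator import TruthModel, simulate_experiment, synthetic_probe_panel
from ncarray.region_selection import CoverageContig


def make_contig(coverage, contig_id="c1", strand="+", read_count=10, seed=0, biotype="unknown"):
    coverage = np.asarray(coverage, dtype=float)
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=len(coverage)))
    return CoverageContig(
        contig_id=contig_id,
        chrom="chrT",
        start=0,
        end=len(coverage),
        strand=strand,
        sequence=seq,
        coverage=coverage,
        read_count=read_count,
        biotype=biotype,
    )


def random_contig(rng, min_len=18, max_len=150):
    length = int(rng.integers(min_len, max_len + 1))
    # mix of flat, peaked and noisy coverage shapes
    shape = rng.integers(0, 3)
    if shape == 0:
        coverage = np.full(length, float(rng.integers(0, 20)))
    elif shape == 1:
        coverage = rng.integers(0, 50, size=length).astype(float)
    else:
        coverage = np.full(length, float(rng.integers(1, 5)))
        lo = int(rng.integers(0, max(1, length - 10)))
        hi = min(length, lo + int(rng.integers(5, 40)))
        coverage[lo:hi] += float(rng.integers(10, 60))
    return make_contig(coverage, contig_id=f"rc{rng.integers(1e9)}", seed=int(rng.integers(1e9)))


@pytest.fixture(scope="session")
def small_panel():
    return synthetic_probe_panel(40, seed=7)


@pytest.fixture(scope="session")
def small_design(small_panel):
    return layout_array(small_panel, n_blocks=4, block_rows=22, block_cols=22, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_panel, small_design):
    candidates = [p.probe_id for p in small_panel if p.role == "signal"]
    truth = TruthModel.generate(candidates, small_design.n_blocks, seed=11)
    scans, sheet, truth_table = simulate_experiment(small_design, truth, n_pairs=3)
    return scans, sheet, truth_table, truth


@pytest.fixture(scope="session")
def noise_free_experiment(small_panel, small_design):
    candidates = [p.probe_id for p in small_panel if p.role == "signal"]
    truth = TruthModel.generate(
        candidates, small_design.n_blocks, seed=13, kappa=0.0, nu=0.0
    ).noise_free()
    scans, sheet, truth_table = simulate_experiment(small_design, truth, n_pairs=3)
    return scans, sheet, truth_table, truth
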