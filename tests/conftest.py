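import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from asmscan.ld_toolkit import LdPanel
from asmscan.pipeline_cli import demo
from asmscan.synthetic_data import SimConfig, SimTruth, simulate


def make_panel(haps: np.ndarray, chrom="1", start=10_000, spacing=1_000) -> LdPanel:
    """Wrap a raw 0/1 matrix in an LdPanel with generic metadata."""
    haps = np.asarray(haps, dtype=np.int8)
    m = haps.shape[1]
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:04d}" for i in range(m)],
            "chrom": [chrom] * m,
            "pos": [start + i * spacing for i in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return LdPanel(haps, variants)


def random_panel(rng: np.random.Generator, n_hap=200, n_var=10, maf_lo=0.1) -> LdPanel:
    """Random polymorphic panel (rejection-samples monomorphic columns)."""
    cols = []
    while len(cols) < n_var:
        p = rng.uniform(maf_lo, 0.5)
        col = (rng.random(n_hap) < p).astype(np.int8)
        if 0 < col.sum() < n_hap:
            cols.append(col)
    return make_panel(np.stack(cols, axis=1))


def catalog_frame(rows) -> pd.DataFrame:
    """Build a schema-complete catalog table from partial row dicts."""
    defaults = {
        "snp_id": "rs1",
        "snp_chrom": "1",
        "snp_pos": 1000,
        "cpg_id": "cg1",
        "cpg_chrom": "1",
        "cpg_pos": 1500,
        "r2_meth": 0.5,
        "meth_effect_allele": "A",
        "meth_direction": 1,
        "tissue": "cerebellum",
        "study": "s1",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo42(tmp_path_factory):
    """One seed-42 end-to-end demo run shared by the whole session."""
    outdir = tmp_path_factory.mktemp("demo42")
    result = demo(42, outdir)
    truth = SimTruth.read(Path(result["paths"]["manifest"]))
    return {"result": result, "truth": truth, "rundir": Path(result["outdir"])}


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small synthetic dataset + manifest (seed 7)."""
    outdir = tmp_path_factory.mktemp("sim7")
    cfg = SimConfig(seed=7, n_blocks=20, n_asm_pairs=80, n_signal_blocks=2)
    paths = simulate(cfg, outdir)
    truth = SimTruth.read(Path(paths["manifest"]))
    return {"config": cfg, "paths": paths, "truth": truth}
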