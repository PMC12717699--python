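"""Synthetic immunotherapy cohorts with known ground truth.

Two fidelity levels make every pipeline stage testable without downloads:

* ``generate_scores`` emits per-cell signature scores directly -- a Beta
  baseline, shifted upward in the planted senescent cells, with an
  overlapping exhausted subpopulation (low senescence, high exhaustion) --
  so the index/grid/ROC stages can be exercised fast;
* ``generate_expression`` emits negative-binomial count matrices in which a
  planted directional signature's up-genes are elevated and down-genes
  suppressed in senescent cells, housekeeping genes are constitutive, and a
  configurable fraction of low-complexity cells exercises the QC filters.

Cohort composition defaults follow the melanoma study design this pipeline
targets: 48 patients with a responder fraction of 18/48, split between CD8+
and CD4+ T-cell compartments, with on the order of a hundred cells per
patient per compartment.  The non-responder group carries a larger senescent
fraction; effect presets "null", "weak" and "strong" fix the
(responder, non-responder) senescent-fraction pair at (0.15, 0.15),
(0.10, 0.20) and (0.05, 0.35) respectively.  Patient-level senescent
fractions are Beta-distributed around the group mean so patients are not
interchangeable.  Everything is reproducible from a single integer seed.

The generator does not attempt doublets, batch effects, ambient RNA or
realistic gene-gene correlation; what passes on it demonstrates the
pipeline's statistical machinery, not robustness to those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .signatures import GeneSignature, default_housekeeping


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort."""

    n_patients: int = 48
    responder_fraction: float = 0.375          # 18 of 48
    cells_per_patient: float = 100.0           # NB mean per cell type
    cells_dispersion: float = 10.0             # NB size parameter
    cell_types: tuple[tuple[str, float], ...] = (("CD8T", 0.5), ("CD4T", 0.5))
    sen_fraction_R: float = 0.10
    sen_fraction_NR: float = 0.20
    sen_fraction_concentration: float = 30.0   # Beta concentration of patient fractions
    score_effect: float = 0.30                 # senescence-score shift in senescent cells
    exh_fraction: float = 0.10
    exhaustion_exclusive: bool = True          # exhausted cells are never senescent
    # expression mode
    n_genes: int = 2000
    up_effect: float = 4.0
    down_effect: float = 4.0
    baseline_dispersion: float = 2.0           # NB size parameter for counts
    low_quality_fraction: float = 0.0          # cells engineered to fail min-genes QC
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "sen_fraction_R", "sen_fraction_NR",
                     "exh_fraction", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


PRESETS: dict[str, dict] = {
    "null": {"sen_fraction_R": 0.15, "sen_fraction_NR": 0.15},
    "weak": {"sen_fraction_R": 0.10, "sen_fraction_NR": 0.20},
    "strong": {"sen_fraction_R": 0.05, "sen_fraction_NR": 0.35},
}


def preset(name: str, **overrides) -> CohortConfig:
    """Named effect preset; extra keyword overrides are applied on top."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    return replace(CohortConfig(**PRESETS[name]), **overrides)


# Beta baselines: mean 0.2, moderately dispersed, support [0, 1].
_BASE_A, _BASE_B = 2.0, 8.0
_EXH_HI_A, _EXH_HI_B = 6.0, 4.0       # exhausted cells' exhaustion: mean 0.6
_SEN_LOW_A, _SEN_LOW_B = 1.5, 13.5    # exhausted cells' senescence: mean 0.1


def _beta_mean_conc(rng: np.random.Generator, mean: float, conc: float, size=None):
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return rng.beta(mean * conc, (1 - mean) * conc, size=size)


def _patient_table(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_r = int(round(cfg.n_patients * cfg.responder_fraction))
    resp = np.array(["R"] * n_r + ["NR"] * (cfg.n_patients - n_r))
    sen_frac = np.where(
        resp == "R",
        _beta_mean_conc(rng, cfg.sen_fraction_R, cfg.sen_fraction_concentration,
                        cfg.n_patients),
        _beta_mean_conc(rng, cfg.sen_fraction_NR, cfg.sen_fraction_concentration,
                        cfg.n_patients),
    )
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in range(cfg.n_patients)],
        "response": resp,
        "sen_fraction": sen_frac,
    })


def _draw_cells(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cell metadata with planted truth states, one block per patient x cell type."""
    patients = _patient_table(cfg, rng)
    rows = []
    mean, size = cfg.cells_per_patient, cfg.cells_dispersion
    p_nb = size / (size + mean)
    for _, pat in patients.iterrows():
        for ct, _prop in cfg.cell_types:
            n = max(int(rng.negative_binomial(size, p_nb)), 1)
            u = rng.random(n)
            state = np.full(n, "normal", dtype=object)
            sf = pat["sen_fraction"]
            state[u < sf] = "senescent"
            if cfg.exhaustion_exclusive:
                state[(u >= sf) & (u < sf + cfg.exh_fraction)] = "exhausted"
            else:
                state[rng.random(n) < cfg.exh_fraction] = "exhausted"
            for j in range(n):
                rows.append((pat["patient_id"], ct, pat["response"], state[j]))
    meta = pd.DataFrame(rows, columns=["patient_id", "cell_type", "response",
                                       "truth_state"])
    meta.insert(0, "cell_id", [f"C{i + 1:06d}" for i in range(len(meta))])
    return meta


def generate_scores(cfg: CohortConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-level cohort: (ScoreTable, metadata with truth labels)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta = _draw_cells(cfg, rng)
    n = len(meta)
    if n == 0:
        raise ValueError("configuration produced zero cells")
    sen = rng.beta(_BASE_A, _BASE_B, n)
    exh = rng.beta(_BASE_A, _BASE_B, n)
    is_sen = (meta["truth_state"] == "senescent").to_numpy()
    is_exh = (meta["truth_state"] == "exhausted").to_numpy()
    sen[is_sen] = np.clip(sen[is_sen] + cfg.score_effect, 0.0, 1.0)
    sen[is_exh] = rng.beta(_SEN_LOW_A, _SEN_LOW_B, int(is_exh.sum()))
    exh[is_exh] = rng.beta(_EXH_HI_A, _EXH_HI_B, int(is_exh.sum()))
    scores = pd.DataFrame(
        {"senescence": sen, "exhaustion": exh},
        index=pd.Index(meta["cell_id"], name="cell_id"),
    )
    return scores, meta


def default_signature() -> GeneSignature:
    """33-up/67-down synthetic placeholder signature shipped with the package."""
    from pathlib import Path

    from .signatures import load_signature

    return load_signature(Path(__file__).parent / "data" / "synthetic_senescence.gmt")


def generate_expression(
    cfg: CohortConfig,
    signature: GeneSignature | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression-level cohort: (counts ExpressionMatrix, metadata with truth).

    Gene panel = planted signature genes + the default housekeeping panel
    (constitutive, high mean) + a few ``MT-`` genes (to exercise the mito
    filter) + filler genes up to ``cfg.n_genes``.  Senescent cells have
    up-gene means multiplied by ``up_effect`` and down-gene means divided by
    ``down_effect``.  A ``low_quality_fraction`` of cells is scaled to a tiny
    library so they fail the 1000-detected-genes filter.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sig = signature or default_signature()
    hk = default_housekeeping()
    mito = [f"MT-SYN{i}" for i in range(1, 6)]
    n_named = len(sig) + len(hk) + len(mito)
    if cfg.n_genes < n_named + 10:
        raise ValueError(f"n_genes={cfg.n_genes} too small for the planted panel "
                         f"({n_named} named genes)")
    filler = [f"GENE{i:05d}" for i in range(cfg.n_genes - n_named)]
    genes = list(sig.up_genes) + list(sig.down_genes) + list(hk.genes) + mito + filler

    meta = _draw_cells(cfg, rng)
    n_cells = len(meta)
    base_mean = rng.lognormal(mean=np.log(2.0), sigma=0.8, size=cfg.n_genes)
    hk_slice = slice(len(sig), len(sig) + len(hk))
    base_mean[hk_slice] = 50.0

    mu = np.repeat(base_mean[:, None], n_cells, axis=1)
    is_sen = (meta["truth_state"] == "senescent").to_numpy()
    mu[: len(sig.up_genes), is_sen] *= cfg.up_effect
    mu[len(sig.up_genes): len(sig), is_sen] /= cfg.down_effect

    low_q = rng.random(n_cells) < cfg.low_quality_fraction
    mu[:, low_q] *= 0.05
    meta["low_quality"] = low_q

    r = cfg.baseline_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    m = ExpressionMatrix(counts, genes, meta["cell_id"].tolist(), "counts")
    return m, meta


def write_cohort(scores: pd.DataFrame, meta: pd.DataFrame, outdir) -> None:
    """Write a score-level cohort as TSVs (scores + metadata with truth)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores.to_csv(outdir / "scores.tsv", sep="\t")
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
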