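"""Synthetic testis scRNA-seq datasets with known ground truth.

The generator emulates the structure the analysis pipeline is built for:
~9 cell types along the spermatogenesis trajectory (somatic hub, cyst and
epithelial cells; germline stem cells through spermatids), per-cell-type
sequencing depth peaking in late spermatogonia / early spermatocytes,
per-cell-type X dosage factors, a distance-decaying expression boost around
chromatin entry sites (CES) on the X in DCC-active cell types, marker genes
elevated in their home type, and testis-specific / testis-biased gene
flags.

Counts are negative binomial with a shared dispersion: for a cell of type
t, gene g,

    count ~ NB(mean = depth_t * w_g * f_{g,t} / Z_t,  dispersion theta)

where w_g is a log-normal baseline mean, f_{g,t} collects the X dosage
factor d_t, the CES boost 1 + beta * exp(-distance / lambda) (X genes in
CES-active types only), marker and gene-class boosts, and Z_t = sum_g
w_g * f_{g,t} normalizes so the expected per-cell depth is exactly
depth_t. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from . import io as _io
from .ces import nearest_ces_distance

__all__ = [
    "CELL_TYPES",
    "SynthConfig",
    "SynthTruth",
    "generate",
    "default_study_config",
    "null_config",
    "write_dataset",
    "load_truth",
]

CELL_TYPES = (
    "hub",
    "cyst",
    "epithelial",
    "GSC/early spermatogonia",
    "late spermatogonia",
    "early spermatocytes",
    "late spermatocytes",
    "early spermatids",
    "late spermatids",
)

CHROM_LENGTHS = {
    "X": 23_500_000,
    "2L": 23_000_000,
    "2R": 25_300_000,
    "3L": 28_100_000,
    "3R": 32_100_000,
    "4": 1_300_000,
    "Y": 3_700_000,
}

# one marker gene per cell type, named after the field's canonical testis
# markers; generated on chromosome 2L
DEFAULT_MARKERS = {
    "hub": ["Fas3"],
    "cyst": ["Rab11"],
    "epithelial": ["MtnA"],
    "GSC/early spermatogonia": ["aub", "bam"],
    "late spermatogonia": ["His2Av"],
    "early spermatocytes": ["fzo"],
    "late spermatocytes": ["twe"],
    "early spermatids": ["Dpy-30L2"],
    "late spermatids": ["p-cup"],
}


@dataclass
class SynthConfig:
    """Generator parameters; defaults come from :func:`default_study_config`."""

    n_cells_per_type: dict
    n_genes: dict
    depth_per_type: dict
    dosage_factor: dict
    ces_active: dict
    ces_positions: list | None = None
    n_ces: int = 60
    ces_beta: float = 6.0
    ces_lambda: float = 4_000.0
    nb_dispersion: float = 2.0
    gene_mean_log2_sd: float = 1.0
    testis_specific_fraction: float = 0.10
    testis_biased_fraction: float = 0.10
    testis_flags_x_only: bool = False
    testis_specific_boost: dict = field(default_factory=dict)
    marker_templates: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    marker_boost: float = 20.0
    chrom_lengths: dict = field(default_factory=lambda: dict(CHROM_LENGTHS))
    seed: int = 0

    def validate(self) -> None:
        for name, mapping in (
            ("n_cells_per_type", self.n_cells_per_type),
            ("depth_per_type", self.depth_per_type),
            ("dosage_factor", self.dosage_factor),
        ):
            for t, v in mapping.items():
                if v <= 0:
                    raise ValueError(f"{name}[{t!r}] must be positive, got {v}")
        for chrom, n in self.n_genes.items():
            if n < 0:
                raise ValueError(f"n_genes[{chrom!r}] must be >= 0")
        if self.ces_beta < 0:
            raise ValueError("ces_beta must be >= 0")
        if self.ces_lambda <= 0:
            raise ValueError("ces_lambda must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("testis_specific_fraction", "testis_biased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        missing = set(self.n_cells_per_type) - set(self.dosage_factor)
        if missing:
            raise ValueError(f"dosage_factor missing cell types {sorted(missing)}")
        missing = set(self.n_cells_per_type) - set(self.depth_per_type)
        if missing:
            raise ValueError(f"depth_per_type missing cell types {sorted(missing)}")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    dosage_factor: dict
    ces_active: dict
    expected_interpretation: dict
    expected_xa_content: dict
    ces_beta: float
    ces_lambda: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_truth(path: str | Path) -> SynthTruth:
    return SynthTruth(**json.loads(Path(path).read_text()))


def _expected_interpretation(d: float) -> str:
    if d > 1.0:
        return "Excess DC"
    if d < 1.0:
        return "No DC"
    return "DC"


def default_study_config(seed: int = 0) -> SynthConfig:
    """A stylized emulation of the two-strain adult-testis study design.

    Dosage factors encode parity in the three somatic types, excess
    compensation in GSC/early spermatogonia (1.8), a borderline deficit in
    late spermatogonia (0.85) and the meiotic/post-meiotic decline
    (0.63-0.77); the CES boost is active in the five compensated types.
    Sizes are scaled to ~1200 cells and 500 genes per major chromosome arm
    so a full analysis runs in about a second. A stylized emulation, not a
    fit to the original libraries.
    """
    return SynthConfig(
        n_cells_per_type={
            "hub": 40,
            "cyst": 120,
            "epithelial": 60,
            "GSC/early spermatogonia": 150,
            "late spermatogonia": 120,
            "early spermatocytes": 200,
            "late spermatocytes": 200,
            "early spermatids": 150,
            "late spermatids": 150,
        },
        n_genes={"X": 500, "2L": 500, "2R": 500, "3L": 500, "3R": 500, "4": 100, "Y": 30},
        depth_per_type={
            "hub": 3_000,
            "cyst": 3_000,
            "epithelial": 3_000,
            "GSC/early spermatogonia": 8_000,
            "late spermatogonia": 15_000,
            "early spermatocytes": 15_000,
            "late spermatocytes": 8_000,
            "early spermatids": 4_000,
            "late spermatids": 2_000,
        },
        dosage_factor={
            "hub": 1.0,
            "cyst": 1.0,
            "epithelial": 1.0,
            "GSC/early spermatogonia": 1.8,
            "late spermatogonia": 0.85,
            "early spermatocytes": 0.66,
            "late spermatocytes": 0.63,
            "early spermatids": 0.70,
            "late spermatids": 0.77,
        },
        ces_active={
            "hub": True,
            "cyst": True,
            "epithelial": True,
            "GSC/early spermatogonia": True,
            "late spermatogonia": True,
            "early spermatocytes": False,
            "late spermatocytes": False,
            "early spermatids": False,
            "late spermatids": False,
        },
        seed=seed,
    )


def null_config(seed: int = 0) -> SynthConfig:
    """Stylized study design with no effects: all dosage factors 1, beta = 0."""
    cfg = default_study_config(seed)
    cfg.dosage_factor = {t: 1.0 for t in cfg.dosage_factor}
    cfg.ces_active = {t: False for t in cfg.ces_active}
    cfg.ces_beta = 0.0
    return cfg


def generate(
    config: SynthConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Draw a dataset: (counts, gene annotation, cell labels, CES table, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # genes
    gene_rows = []
    marker_names = {
        name: t for t, names in config.marker_templates.items() for name in names
    }
    marker_pool = list(marker_names)
    for chrom in config.n_genes:
        length = config.chrom_lengths[chrom]
        n = config.n_genes[chrom]
        starts = rng.integers(1, max(2, length - 10_000), size=n)
        spans = rng.integers(500, 5_000, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            if chrom == "2L" and marker_pool:
                gid = marker_pool.pop(0)
            else:
                gid = f"g{chrom}_{i:04d}"
            gene_rows.append(
                (gid, chrom, int(starts[i]), int(starts[i] + spans[i]), strands[i])
            )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id", drop=False)
    n_genes = len(genes)

    # gene-class flags (markers stay unflagged so rules remain testable)
    u = rng.random(n_genes)
    is_marker = genes["gene_id"].isin(marker_names).to_numpy()
    flaggable = ~is_marker
    if config.testis_flags_x_only:
        flaggable &= (genes["chromosome"] == "X").to_numpy()
    ts = (u < config.testis_specific_fraction) & flaggable
    tb = (
        (u >= config.testis_specific_fraction)
        & (u < config.testis_specific_fraction + config.testis_biased_fraction)
        & flaggable
    )
    genes["testis_specific"] = ts
    genes["testis_biased"] = tb

    # CES sites: evenly spaced unless positions are given
    if config.ces_positions is None:
        positions = np.linspace(
            50_000, config.chrom_lengths["X"] - 50_000, config.n_ces
        ).astype(np.int64)
    else:
        positions = np.asarray(sorted(config.ces_positions), dtype=np.int64)
    ces = pd.DataFrame(
        {
            "chromosome": "X",
            "start": positions,
            "end": positions + 200,
            "site_id": [f"CES{i:03d}" for i in range(len(positions))],
        }
    )

    # per-X-gene CES boost; geometric-mean-centred across X genes so that the
    # boost redistributes X output toward CES-proximal genes without shifting
    # the chromosome-wide level - d_t stays the net X:A effect
    x_mask = (genes["chromosome"] == "X").to_numpy()
    boost = np.ones(n_genes)
    if len(ces) and config.ces_beta > 0:
        dist = nearest_ces_distance(genes, ces)
        d = dist.loc[genes.index[x_mask], "distance"].to_numpy(dtype=np.float64)
        raw_boost = 1.0 + config.ces_beta * np.exp(-d / config.ces_lambda)
        boost[x_mask] = raw_boost / np.exp(np.mean(np.log(raw_boost)))

    # baseline gene means (log-normal)
    ln2 = np.log(2.0)
    w = np.exp(rng.normal(0.0, config.gene_mean_log2_sd * ln2, size=n_genes))

    cell_types = list(config.n_cells_per_type)
    ts_boost = {
        t: config.testis_specific_boost.get(t, 1.0) for t in cell_types
    }

    blocks = []
    labels_rows = []
    expected_xa = {}
    theta = config.nb_dispersion
    cell_counter = 0
    for t in cell_types:
        f = np.ones(n_genes)
        f[x_mask] *= config.dosage_factor[t]
        if config.ces_active.get(t, False):
            f[x_mask] *= boost[x_mask]
        if ts_boost[t] != 1.0:
            f[ts] *= ts_boost[t]
        for name in config.marker_templates.get(t, []):
            if name in genes.index:
                f[genes.index.get_loc(name)] *= config.marker_boost
        wf = w * f
        z = wf.sum()
        mean = config.depth_per_type[t] * wf / z

        a_mask = genes["chromosome"].isin(["2L", "2R", "3L", "3R", "4"]).to_numpy()
        expected_xa[t] = float(wf[x_mask].sum() / wf[a_mask].sum())

        n_cells = config.n_cells_per_type[t]
        mean_mat = np.broadcast_to(mean, (n_cells, n_genes))
        p = theta / (theta + mean_mat)
        counts = rng.negative_binomial(theta, p)
        blocks.append(sparse.csr_matrix(counts))
        for _ in range(n_cells):
            labels_rows.append((f"cell_{cell_counter:05d}", t, "simulated"))
            cell_counter += 1

    x = sparse.vstack(blocks).astype(np.int64)
    labels = pd.DataFrame(labels_rows, columns=["barcode", "cell_type", "strain"])
    labels = labels.set_index("barcode", drop=False)
    adata = ad.AnnData(X=x.tocsr())
    adata.obs_names = labels["barcode"].tolist()
    adata.var_names = genes["gene_id"].tolist()

    truth = SynthTruth(
        dosage_factor=dict(config.dosage_factor),
        ces_active=dict(config.ces_active),
        expected_interpretation={
            t: _expected_interpretation(config.dosage_factor[t]) for t in cell_types
        },
        expected_xa_content=expected_xa,
        ces_beta=config.ces_beta,
        ces_lambda=config.ces_lambda,
        seed=config.seed,
    )
    return adata, genes, labels, ces, truth


def write_dataset(
    out_dir: str | Path,
    adata: ad.AnnData,
    genes: pd.DataFrame,
    labels: pd.DataFrame,
    ces: pd.DataFrame,
    truth: SynthTruth | None = None,
) -> None:
    """Write a generated dataset in the exact formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_count_matrix(
        adata, out / "matrix.mtx", out / "barcodes.tsv", out / "genes.tsv"
    )
    _io.write_gene_annotation(genes, out / "gene_annotation.tsv")
    _io.write_cell_labels(labels, out / "cell_labels.tsv")
    _io.write_ces_bed(ces, out / "ces.bed")
    if truth is not None:
        truth.to_json(out / "truth.json")
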