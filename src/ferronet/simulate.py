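"""Seeded generators for cohort, cell/spot and platform-list data.

These emulate the statistical structure the pipeline assumes — matched
N/IC/IF/M samples per patient, genes grouped into correlated modules that
are enriched for named signatures, per-site log2 T/N shifts that rise from
the inner core over the invasive front to metastasis for designated
modules, and overdispersed spot counts with region labels — together with
ground-truth records so every stage can be checked against what was
planted.  Every generator is a pure function of its spec and seed.

The cohort model, per gene g in module m, patient p, site s (log2 scale):

    x = baseline_g + u_p + noise_sd * (lambda_m f_{m,p,s}
                                       + sqrt(1 - lambda_m^2) eps) + delta_{m,s}

with lambda_m = sqrt(r) so the within-module correlation of the module
term is exactly r, f and eps standard normal, and u_p a patient effect
(sd 0.3) shared by all genes of a patient's samples.  The site factor f is
redrawn per site within a patient, so tumor/normal contrasts are driven by
the planted shifts delta rather than shared factors.  Background genes
carry baseline + u_p + noise_sd * eps.  The matrix is emitted on the TPM
scale as 2^x - 1 clipped at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BULK_SITES,
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    TUMOR_SITES,
    ValidationError,
)

PATIENT_SD = 0.3  # shared per-patient effect on the log2 scale


@dataclass
class ModuleSpec:
    """One planted coexpression module."""

    size: int
    r: float = 0.64                     # target within-module correlation
    signature: str | None = None        # named signature the module carries
    shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)  # delta IC, IF, M

    def __post_init__(self) -> None:
        if not (0 <= self.r < 1):
            raise ValidationError("module correlation target must lie in [0, 1)")
        if self.size < 1:
            raise ValidationError("module size must be positive")


@dataclass
class CohortSpec:
    """Design of a synthetic matched-site bulk cohort."""

    n_patients: int = 15
    n_genes: int = 1200
    modules: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 1

    def __post_init__(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValidationError("module sizes exceed the gene count")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """What was planted: module membership, signatures, shifts, regions."""

    module_of: dict = field(default_factory=dict)         # gene -> module int
    signature_of_module: dict = field(default_factory=dict)
    shifts: dict = field(default_factory=dict)            # module -> {site: delta}
    region_of: dict = field(default_factory=dict)         # spot -> region
    de_genes: list = field(default_factory=list)          # planted DE genes
    effect: float = 0.0

    def to_json(self, path) -> None:
        d = {
            "module_of": self.module_of,
            "signature_of_module": {str(k): v for k, v in
                                    self.signature_of_module.items()},
            "shifts": {str(k): v for k, v in self.shifts.items()},
            "region_of": self.region_of,
            "de_genes": self.de_genes,
            "effect": self.effect,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def default_modules() -> tuple[ModuleSpec, ...]:
    """The five planted modules of the default cohort.

    Two signature modules carry coupled, gradually increasing IC -> IF -> M
    shifts (ferroptosis-like and inflammation-like); one is shifted flat,
    one not at all, one decreasing — so both the positive and the negative
    branches of the gradient decision are represented.  Per-step shifts of
    about one log2 unit keep the planted medians clear of the
    between-patient sampling noise of a 15-patient median.
    """
    return (
        ModuleSpec(120, 0.64, "ferroptosis", (0.5, 1.5, 2.5)),
        ModuleSpec(100, 0.64, "inflammation", (0.4, 1.2, 2.0)),
        ModuleSpec(90, 0.64, "tumor_inflammation", (0.5, 0.5, 0.5)),
        ModuleSpec(80, 0.64, "EMT", (0.0, 0.0, 0.0)),
        ModuleSpec(60, 0.64, "ISG", (-0.3, -0.6, -0.9)),
    )


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Simulate a matched-site bulk cohort on the TPM scale."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    samples, patients, sites = [], [], []
    for p in range(1, spec.n_patients + 1):
        for s in BULK_SITES:
            samples.append(f"P{p:02d}_{s}")
            patients.append(f"P{p:02d}")
            sites.append(s)
    n_samp = len(samples)

    module_of = np.zeros(spec.n_genes, dtype=int)
    start = 0
    for m, mod in enumerate(spec.modules, start=1):
        module_of[start:start + mod.size] = m
        start += mod.size

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    u = rng.normal(0.0, PATIENT_SD, spec.n_patients)
    x = baseline[:, None] + np.zeros((spec.n_genes, n_samp))
    for j, (pat, site) in enumerate(zip(patients, sites)):
        x[:, j] += u[int(pat[1:]) - 1]

    background = np.flatnonzero(module_of == 0)
    x[background] += spec.noise_sd * rng.normal(size=(background.size, n_samp))

    site_index = {s: i for i, s in enumerate(TUMOR_SITES)}
    for m, mod in enumerate(spec.modules, start=1):
        rows = np.flatnonzero(module_of == m)
        lam = np.sqrt(mod.r)
        f = rng.normal(size=n_samp)  # one factor per (patient, site) column
        x[rows] += spec.noise_sd * (
            lam * f[None, :]
            + np.sqrt(1.0 - mod.r) * rng.normal(size=(rows.size, n_samp))
        )
        for j, site in enumerate(sites):
            if site in site_index:
                x[rows, j] += mod.shifts[site_index[site]]

    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    matrix = ExpressionMatrix(genes, samples, tpm, "TPM")
    ann = SampleAnnotation(pd.DataFrame({
        "sample_id": samples, "patient_id": patients, "site": sites,
    }))
    truth = SyntheticTruth(
        module_of={g: int(m) for g, m in zip(genes, module_of)},
        signature_of_module={m: mod.signature
                             for m, mod in enumerate(spec.modules, start=1)},
        shifts={m: dict(zip(TUMOR_SITES, mod.shifts))
                for m, mod in enumerate(spec.modules, start=1)},
    )
    return matrix, ann, truth


def signature_collection(
    truth: SyntheticTruth,
    spec: CohortSpec,
    genes_per_set: int = 40,
    extra_background: int = 20,
    seed: int | None = None,
) -> GeneSetCollection:
    """Signature gene sets matched to the planted modules.

    Each signature set takes ``genes_per_set`` members from its module and
    ``extra_background`` genes from outside every module, emulating
    signatures that only partially overlap any one module.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    by_module: dict[int, list[str]] = {}
    background = [g for g, m in truth.module_of.items() if m == 0]
    for g, m in truth.module_of.items():
        if m > 0:
            by_module.setdefault(m, []).append(g)
    sets = {}
    for m, sig in truth.signature_of_module.items():
        if sig is None:
            continue
        members = sorted(by_module[m])
        take = min(genes_per_set, len(members))
        chosen = list(rng.choice(members, size=take, replace=False))
        chosen += list(rng.choice(sorted(background), size=extra_background,
                                  replace=False))
        sets[sig] = frozenset(chosen)
    return GeneSetCollection("signatures", sets)


def simulate_spots(
    n_spots: int = 400,
    n_genes: int = 1000,
    front_fraction: float = 0.5,
    n_signature_genes: int = 50,
    effect: float = 1.5,
    library_size: float = 20000.0,
    dispersion: float = 0.5,
    signature_boost: float = 8.0,
    seed: int = 1,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Simulate a spot lattice with a planted front-vs-core signature shift.

    Counts are negative binomial (gamma-Poisson with gene-level means and
    shape 1/dispersion).  Signature genes get a ``signature_boost``-fold
    higher base abundance plus a ``2^effect``-fold increase in front spots,
    which are placed on the lattice perimeter; core spots fill the inside.
    """
    if library_size <= 0:
        raise ValidationError("library size must be positive")
    if not (0 <= front_fraction <= 1):
        raise ValidationError("front fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    sig_genes = genes[:n_signature_genes]

    side = int(np.ceil(np.sqrt(n_spots)))
    coords = [(r, c) for r in range(side) for c in range(side)][:n_spots]
    ring = [min(r, c, side - 1 - r, side - 1 - c) for r, c in coords]
    order = np.argsort(np.array(ring), kind="stable")  # perimeter first
    n_front = int(round(front_fraction * n_spots))
    region = np.empty(n_spots, dtype=object)
    region[order[:n_front]] = "front"
    region[order[n_front:]] = "core"
    barcodes = [f"SPOT{i:04d}" for i in range(1, n_spots + 1)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[:n_signature_genes] *= signature_boost
    props = base / base.sum()
    mu = np.tile(props[:, None] * library_size, (1, n_spots))
    mu[:n_signature_genes, region == "front"] *= 2.0 ** effect
    shape = 1.0 / dispersion if dispersion > 0 else np.inf
    if np.isfinite(shape):
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    matrix = ExpressionMatrix(genes, barcodes, counts, "counts")
    ann = SampleAnnotation(pd.DataFrame({
        "sample_id": barcodes,
        "patient_id": "SPATIAL1",
        "site": region,
        "x": [c for _, c in coords],
        "y": [r for r, _ in coords],
    }))
    truth = SyntheticTruth(
        region_of=dict(zip(barcodes, region)),
        de_genes=list(sig_genes),
        effect=float(effect),
    )
    return matrix, ann, truth


def platform_gene_lists(
    seed: int = 1,
    n_spatial: int = 1500,
    n_bulk: int = 539,
    n_overlap: int = 42,
    universe: int = 20000,
) -> tuple[list[str], list[str]]:
    """Synthetic stand-in for the two platform gene lists.

    The real lists (top spatial up-regulated genes and fold-change-filtered
    bulk genes) live in supplementary data that is not redistributable, so
    this generates a synthetic pair with the published structure: a
    ``n_spatial``-gene list, an ``n_bulk``-gene list and exactly
    ``n_overlap`` genes common to both, drawn from a synthetic namespace.
    """
    if n_overlap > min(n_spatial, n_bulk):
        raise ValidationError("overlap cannot exceed either list size")
    if n_spatial + n_bulk - n_overlap > universe:
        raise ValidationError("universe too small for the requested lists")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(universe)
    shared = pool[:n_overlap]
    a_only = pool[n_overlap:n_spatial]
    b_only = pool[n_spatial:n_spatial + n_bulk - n_overlap]
    names = np.array([f"SG{i:05d}" for i in range(universe)])
    list_a = list(names[rng.permutation(np.concatenate([shared, a_only]))])
    list_b = list(names[rng.permutation(np.concatenate([shared, b_only]))])
    return list_a, list_b


def default_fixture(out_dir, seed: int = 1) -> dict:
    """Write the small end-to-end fixture bundle and return its paths.

    The bundle holds the 1200-gene x 60-sample matched cohort with five
    planted modules, the five-signature GMT, a 400-spot lattice with a
    planted front shift, and the ground-truth JSON.  Regenerating with the
    same seed reproduces every file byte for byte.
    """
    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=seed, modules=default_modules())
    matrix, ann, truth = simulate_cohort(spec)
    sigs = signature_collection(truth, spec)
    spots, spot_ann, spot_truth = simulate_spots(seed=seed)

    paths = {
        "expression": out / "cohort_expression.tsv",
        "annotation": out / "cohort_annotation.tsv",
        "signatures": out / "signatures.gmt",
        "spots_mtx": out / "spots_matrix.mtx",
        "spots_features": out / "spots_features.tsv",
        "spots_barcodes": out / "spots_barcodes.tsv",
        "spots_annotation": out / "spots_annotation.tsv",
        "truth": out / "truth.json",
        "spot_truth": out / "spot_truth.json",
    }
    fio.write_expression_table(matrix, paths["expression"])
    fio.write_annotation(ann, paths["annotation"])
    fio.write_gmt(sigs, paths["signatures"])
    fio.write_sparse_counts(spots, paths["spots_mtx"], paths["spots_features"],
                            paths["spots_barcodes"])
    fio.write_annotation(spot_ann, paths["spots_annotation"])
    truth.to_json(paths["truth"])
    spot_truth.to_json(paths["spot_truth"])
    return {k: str(v) for k, v in paths.items()}
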