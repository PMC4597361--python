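"""Synthetic multi-cohort expression data with planted informative pairs.

The generator emulates the statistical structure the search method assumes:
several independent cohorts (training, filtration, validation) drawn from
the same class-conditional distributions, a planted "low individual, high
joint" gene pair, a sea of class-independent noise probesets, optional
probesets constructed to fail each filtration rule, and survival times wired
so that outcome-class assignment reproduces the intended positive /
negative / gray labels.

The planted pair follows the classic two-gene picture: gene 1 is shifted
between classes by ``delta_marginal`` (in units of its within-class SD) but
its marginals overlap; gene 2 is barely shifted (``delta_gene2`` SD, low
individual differential expression); the two are strongly correlated within
class so that the *difference* axis separates the classes by ``delta_joint``
difference-axis SDs — a pair that is nearly uninformative gene-by-gene yet
close to perfectly separable jointly. Class-conditional distributions are
bivariate Gaussian on the log2 scale, the minimal model consistent with that
picture.

Every dataset is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import GRAY, NEGATIVE, POSITIVE, ClassLabels, CohortSplit
from .errors import ValidationError
from .io import MICROARRAY, RNASEQ, ExpressionMatrix, PhenotypeTable

DEFAULT_COHORT_SIZES = {
    "training": 100,
    "filtration_1": 100,
    "filtration_2": 100,
    "validation": 100,
}

_GENE1_BASE = 8.5  # log2 baseline of the planted pair's first gene
_GENE2_BASE = 9.0


@dataclass(frozen=True)
class PlantedPairSpec:
    """Parameters of one planted informative pair.

    ``delta_marginal`` — standardized between-class shift of gene 1;
    ``delta_gene2`` — shift of gene 2, kept small (low individual DE);
    ``delta_joint`` — standardized separation along the gene1 − gene2 axis;
    ``rho`` — within-class correlation. By default (``rho=None``) the
    correlation is solved from ``delta_joint``:

        rho = 1 − ((delta_marginal − delta_gene2) / delta_joint)² / 2

    (≈ 0.98 at the defaults). An explicitly supplied rho takes precedence,
    in which case the realized joint separation follows from it.
    ``delta_joint = 0`` means "no joint signal": the genes are generated
    independently (rho = 0).
    """

    delta_marginal: float = 1.0
    delta_joint: float = 4.0
    rho: float | None = None
    delta_gene2: float = 0.2
    n_pos: int = 100
    n_neg: int = 100

    def resolve(self) -> tuple[float, float]:
        """Return (rho, realized delta_joint) after consistency resolution."""
        if self.delta_marginal < 0 or self.delta_joint < 0:
            raise ValidationError("deltas must be non-negative")
        gap = self.delta_marginal - self.delta_gene2
        if self.rho is not None:
            rho = float(self.rho)
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"rho={rho} outside (-1, 1)")
            realized = gap / math.sqrt(2.0 * (1.0 - rho)) if gap else 0.0
            return rho, realized
        if self.delta_joint == 0:
            return 0.0, 0.0
        rho = 1.0 - (gap / self.delta_joint) ** 2 / 2.0
        if not -1.0 < rho < 1.0:
            raise ValidationError(
                "delta_joint too small for the marginal gap; implied rho "
                f"{rho:.3f} outside (-1, 1)"
            )
        return rho, self.delta_joint


@dataclass
class SyntheticLedger:
    """Ground truth of a generated dataset; fully determines it given the seed."""

    seed: int
    planted_specs: list[PlantedPairSpec]
    planted_probesets: list[tuple[str, str]]
    noise_probesets: list[str] = field(default_factory=list)
    fail_low_probesets: list[str] = field(default_factory=list)
    fail_ratio_probesets: list[str] = field(default_factory=list)
    no_symbol_probesets: list[str] = field(default_factory=list)
    classes: dict[str, pd.Series] = field(default_factory=dict)
    hidden_class: dict[str, pd.Series] = field(default_factory=dict)
    planted_latents: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def fail_probesets(self) -> list[str]:
        return (
            self.fail_low_probesets
            + self.fail_ratio_probesets
            + self.no_symbol_probesets
        )

    def class_counts(self, role: str) -> dict[str, int]:
        c = self.classes[role].value_counts()
        return {k: int(c.get(k, 0)) for k in (POSITIVE, NEGATIVE, GRAY)}

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_specs": [vars(s) | {} for s in self.planted_specs],
            "planted_probesets": [list(t) for t in self.planted_probesets],
            "noise_probesets": self.noise_probesets,
            "fail_low_probesets": self.fail_low_probesets,
            "fail_ratio_probesets": self.fail_ratio_probesets,
            "no_symbol_probesets": self.no_symbol_probesets,
            "classes": {r: s.to_dict() for r, s in self.classes.items()},
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _pair_means(spec: PlantedPairSpec):
    """Class means (negative, positive) for (gene1, gene2) on log2 scale."""
    neg = np.array([_GENE1_BASE, _GENE2_BASE])
    pos = neg + np.array([spec.delta_marginal, spec.delta_gene2])
    return neg, pos


def _pair_cov(rho: float) -> np.ndarray:
    return np.array([[1.0, rho], [rho, 1.0]])


def _draw_pair_values(
    spec: PlantedPairSpec, classes01: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(2, n) planted-pair values for per-sample 0/1 hidden classes."""
    rho, _ = spec.resolve()
    neg, pos = _pair_means(spec)
    L = np.linalg.cholesky(_pair_cov(rho))
    z = rng.standard_normal((len(classes01), 2)) @ L.T
    means = np.where(classes01[:, None] == 1, pos[None, :], neg[None, :])
    return (means + z).T


def generate_figure1_pair(
    spec: PlantedPairSpec | None = None, seed: int = 0
) -> tuple[ExpressionMatrix, ClassLabels, SyntheticLedger]:
    """One planted pair, two classes, no gray zone — the minimal showcase.

    Gene 1 is visibly but uselessly shifted, gene 2 almost not at all, yet a
    linear rule on the two together separates the classes nearly perfectly.
    """
    spec = spec or PlantedPairSpec()
    if spec.n_pos < 2 or spec.n_neg < 2:
        raise ValidationError("need at least 2 samples per class")
    spec.resolve()  # validates rho
    rng = np.random.default_rng(seed)
    classes01 = np.r_[np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    values = _draw_pair_values(spec, classes01, rng)
    sample_ids = [f"fig1_s{i:03d}" for i in range(len(classes01))]
    probesets = ("GENE1_at", "GENE2_at")
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(probesets), columns=sample_ids),
        platform=MICROARRAY,
        annotation={"GENE1_at": "GENE1", "GENE2_at": "GENE2"},
    )
    labels = ClassLabels(
        pd.Series(
            np.where(classes01 == 1, POSITIVE, NEGATIVE),
            index=sample_ids,
            name="label",
        )
    )
    ledger = SyntheticLedger(
        seed=seed,
        planted_specs=[spec],
        planted_probesets=[probesets],
        classes={"figure1": labels.labels.copy()},
        hidden_class={"figure1": pd.Series(classes01, index=sample_ids)},
        planted_latents={"figure1": values.copy()},
        params={"kind": "figure1"},
    )
    return matrix, labels, ledger


def _survival_times(
    labels: np.ndarray,
    rng: np.random.Generator,
    event_window: float,
    free_window: float,
):
    """(time_years, event_observed) consistent with the intended class labels.

    Positives: event from an exponential truncated to (0, event_window].
    Negatives: censored uniformly beyond free_window. Gray: alternately
    censored before free_window or an event after event_window.
    """
    n = len(labels)
    times = np.empty(n)
    events = np.zeros(n, dtype=bool)
    scale = event_window / 2.0
    gray_toggle = True
    for i, lab in enumerate(labels):
        if lab == POSITIVE:
            u = rng.random()
            cap = 1.0 - math.exp(-event_window / scale)
            times[i] = -scale * math.log(1.0 - u * cap)
            events[i] = True
        elif lab == NEGATIVE:
            times[i] = free_window + rng.uniform(0.0, 3.0)
        else:  # gray
            if gray_toggle:
                times[i] = rng.uniform(0.5, free_window - 0.05)
            else:
                times[i] = rng.uniform(event_window + 0.05, free_window + 2.0)
                events[i] = True
            gray_toggle = not gray_toggle
    return times, events


def _passes_filter_rows(values: np.ndarray, nongray: np.ndarray) -> np.ndarray:
    """Which rows would survive the expression/ratio filter on non-gray samples."""
    sub = values[:, nongray]
    return (sub.max(axis=1) >= 7.0) & (sub.max(axis=1) - sub.min(axis=1) >= 1.0)


def generate_cohort_split(
    n_noise_probesets: int = 200,
    planted: list[PlantedPairSpec] | None = None,
    cohort_sizes: dict[str, int] | None = None,
    gray_fraction: float = 0.2,
    seed: int = 0,
    pos_fraction: float = 1.0 / 3.0,
    n_fail_low: int = 0,
    n_fail_ratio: int = 0,
    n_fail_nosymbol: int = 0,
    event_window: float = 5.0,
    free_window: float = 7.0,
) -> tuple[CohortSplit, dict[str, PhenotypeTable], SyntheticLedger]:
    """Generate a full multi-cohort split with planted structure and ground truth.

    All cohorts share the planted class-conditional distributions and the
    probeset universe; noise probesets are class-independent Gaussians whose
    training values are guaranteed to pass the expression and ratio filters,
    while the ``n_fail_*`` blocks are constructed to fail exactly one rule
    each (low expression, low max/min ratio, missing gene symbol). Survival
    times are drawn so that outcome-class assignment with the same windows
    reproduces the intended labels. Returns the split, per-role phenotype
    tables, and the ledger of ground truth.
    """
    if planted is None:
        planted = [PlantedPairSpec()]
    cohort_sizes = dict(cohort_sizes or DEFAULT_COHORT_SIZES)
    if not 0.0 <= gray_fraction <= 0.5:
        raise ValidationError("gray_fraction must lie in [0, 0.5]")
    for role, n in cohort_sizes.items():
        if n < 10:
            raise ValidationError(f"cohort {role!r} too small ({n} < 10)")
    if "training" not in cohort_sizes:
        raise ValidationError("cohort_sizes must include 'training'")
    for spec in planted:
        spec.resolve()

    rng = np.random.default_rng(seed)

    # --- probeset universe -------------------------------------------------
    annotation: dict[str, str] = {}
    planted_ids: list[tuple[str, str]] = []
    for j in range(len(planted)):
        a, b = f"PLT{j + 1:03d}A_at", f"PLT{j + 1:03d}B_at"
        planted_ids.append((a, b))
        annotation[a] = f"PGENE{j + 1}A"
        annotation[b] = f"PGENE{j + 1}B"
    noise_ids = [f"NSE{i + 1:05d}_at" for i in range(n_noise_probesets)]
    for i, ps in enumerate(noise_ids):
        annotation[ps] = f"NGENE{i + 1}"
    low_ids = [f"FLO{i + 1:03d}_at" for i in range(n_fail_low)]
    ratio_ids = [f"FRA{i + 1:03d}_at" for i in range(n_fail_ratio)]
    nosym_ids = [f"FNS{i + 1:03d}_at" for i in range(n_fail_nosymbol)]
    for i, ps in enumerate(low_ids):
        annotation[ps] = f"LGENE{i + 1}"
    for i, ps in enumerate(ratio_ids):
        annotation[ps] = f"RGENE{i + 1}"
    all_ids = (
        [p for pair in planted_ids for p in pair]
        + noise_ids
        + low_ids
        + ratio_ids
        + nosym_ids
    )

    noise_mean = rng.uniform(7.5, 11.5, size=n_noise_probesets)
    noise_sd = rng.uniform(0.4, 0.8, size=n_noise_probesets)

    roles = list(cohort_sizes)
    matrices: dict[str, ExpressionMatrix] = {}
    labels: dict[str, ClassLabels] = {}
    phenos: dict[str, PhenotypeTable] = {}
    ledger = SyntheticLedger(
        seed=seed,
        planted_specs=list(planted),
        planted_probesets=planted_ids,
        noise_probesets=noise_ids,
        fail_low_probesets=low_ids,
        fail_ratio_probesets=ratio_ids,
        no_symbol_probesets=nosym_ids,
        params={
            "cohort_sizes": cohort_sizes,
            "gray_fraction": gray_fraction,
            "pos_fraction": pos_fraction,
            "event_window": event_window,
            "free_window": free_window,
            "n_noise_probesets": n_noise_probesets,
        },
    )

    for role in roles:
        n = cohort_sizes[role]
        n_gray = int(round(gray_fraction * n))
        n_rest = n - n_gray
        n_pos = max(2, int(round(pos_fraction * n_rest)))
        n_neg = n_rest - n_pos
        if n_neg < 2:
            raise ValidationError(f"cohort {role!r} leaves fewer than 2 negatives")
        lab = np.array(
            [POSITIVE] * n_pos + [NEGATIVE] * n_neg + [GRAY] * n_gray, dtype=object
        )
        perm = rng.permutation(n)
        lab = lab[perm]
        sample_ids = [f"{role}_s{i:03d}" for i in range(n)]
        # hidden class drives expression; gray samples are an ambiguous mixture
        hidden = np.where(
            lab == POSITIVE, 1, np.where(lab == NEGATIVE, 0, -1)
        ).astype(int)
        gray_mask = hidden == -1
        hidden[gray_mask] = (rng.random(gray_mask.sum()) < 0.5).astype(int)
        nongray = lab != GRAY

        blocks = []
        latents = []
        for spec in planted:
            vals = _draw_pair_values(spec, hidden, rng)
            if role == "training":
                while not _passes_filter_rows(vals, nongray).all():
                    vals = _draw_pair_values(spec, hidden, rng)
            latents.append(vals)
            blocks.append(vals)
        if n_noise_probesets:
            nv = noise_mean[:, None] + noise_sd[:, None] * rng.standard_normal(
                (n_noise_probesets, n)
            )
            if role == "training":
                bad = ~_passes_filter_rows(nv, nongray)
                while bad.any():
                    redraw = noise_mean[bad, None] + noise_sd[
                        bad, None
                    ] * rng.standard_normal((int(bad.sum()), n))
                    nv[bad] = redraw
                    bad = ~_passes_filter_rows(nv, nongray)
            blocks.append(nv)
        if n_fail_low:
            lv = np.minimum(
                rng.normal(5.5, 0.4, size=(n_fail_low, n)), 6.9
            )  # max < 7 everywhere -> "constantly low"
            blocks.append(lv)
        if n_fail_ratio:
            base = rng.uniform(8.0, 10.0, size=(n_fail_ratio, 1))
            rv = base + np.clip(
                rng.normal(0.0, 0.2, size=(n_fail_ratio, n)), -0.45, 0.45
            )  # log2 range < 1 -> linear ratio < 2
            blocks.append(rv)
        if n_fail_nosymbol:
            sv = rng.uniform(7.5, 11.5, size=(n_fail_nosymbol, 1)) + 0.5 * (
                rng.standard_normal((n_fail_nosymbol, n))
            )
            blocks.append(sv)
        values = np.vstack(blocks)

        matrices[role] = ExpressionMatrix(
            pd.DataFrame(values, index=all_ids, columns=sample_ids),
            platform=MICROARRAY,
            annotation=annotation,
        )
        lab_series = pd.Series(lab, index=sample_ids, name="label")
        labels[role] = ClassLabels(lab_series)
        times, events = _survival_times(lab, rng, event_window, free_window)
        phenos[role] = PhenotypeTable(
            pd.DataFrame(
                {
                    "event_observed": events,
                    "time_years": times,
                    "er_status": "positive",
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )
        ledger.classes[role] = lab_series.copy()
        ledger.hidden_class[role] = pd.Series(hidden, index=sample_ids)
        ledger.planted_latents[role] = np.vstack(latents) if latents else np.empty((0, n))

    filtration_roles = [r for r in roles if r.startswith("filtration")]
    split = CohortSplit(
        training=(matrices["training"], labels["training"]),
        filtration=[(matrices[r], labels[r]) for r in filtration_roles],
        validation=(
            (matrices["validation"], labels["validation"])
            if "validation" in matrices
            else None
        ),
    )
    return split, phenos, ledger


def generate_rnaseq_like(
    ledger: SyntheticLedger,
    role: str = "validation",
    library_scale: float = 1.0,
    measurement_sd: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Re-express a cohort's planted genes on a non-negative RPKM-like scale.

    The same latent log2 expression that produced the microarray values is
    mapped to RPKM = library_scale · 2^(latent − 6 + ε), ε ~ N(0,
    measurement_sd) — a lognormal read-out around the class-conditional
    means. Values are linear-scale RPKM (feed through ``log2(RPKM + 1)`` for
    classification); because the map is monotone, class ordering of decision
    values is preserved across platforms.
    """
    if role not in ledger.planted_latents:
        raise ValidationError(f"ledger has no cohort {role!r}")
    rng = np.random.default_rng(seed)
    latent = ledger.planted_latents[role]
    noise = measurement_sd * rng.standard_normal(latent.shape)
    rpkm = library_scale * np.exp2(latent - 6.0 + noise)
    gene_ids = []
    for a, b in ledger.planted_probesets:
        gene_ids += [a.replace("_at", "_gene"), b.replace("_at", "_gene")]
    sample_ids = list(ledger.classes[role].index)
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=gene_ids, columns=sample_ids),
        platform=RNASEQ,
        annotation={},
    )
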