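"""Fitting the per-substitution similarity ``s`` from binding data.

The pipeline mirrors how ``s`` is derived from a SKEMPI-style database of
mutational binding measurements:

1. parse single-substitution records with dissociation constants for both
   members of each reference/variant pair; ``|ddG| = RT |ln(Kd_wt/Kd_mut)|``;
2. split records into interface *core* and *noncore* substitutions (core
   substitutions perturb binding more) and combine the two |ddG|
   distributions into a master distribution with a 0.15:0.85 weighting,
   the approximate proportion of core vs noncore residues in CDR3s;
3. remove ascertainment-biased extreme values (|ddG| > 3.2 kcal/mol by
   default; experimenters over-study substitutions with dramatic effects);
4. evaluate candidate models of |ddG| by bootstrap over random 2:1
   training:test splits, minimizing held-out RMSE: a mean model (predict
   the training-set mean), and linear models on biophysical property
   differences of the substituted residues, raw or PCA-reduced;
5. the selected model's mean |ddG| implies ``s = exp(-mean/RT)``.

The entry point is :class:`SubstitutionEffectModel`, whose :meth:`fit`
returns a :class:`SubstitutionEffectResults` carrying per-model RMSE
(mean +/- SD over replicates), the implied ``s`` with a bootstrap CI, and
a ``summary()`` table.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, FormatError, ValidationError
from .similarity import STANDARD_THERMO, ThermoConstants

logger = logging.getLogger(__name__)

__all__ = [
    "DdgRecord",
    "ParsedDdg",
    "WeightedSample",
    "ExponentialFit",
    "FitReport",
    "MultiplicativeCheck",
    "DEFAULT_REGION_MAP",
    "parse_skempi_like",
    "remove_extremes",
    "master_distribution",
    "fit_exponential",
    "compare_distributions",
    "load_property_table",
    "property_preprocessing",
    "bootstrap_model_selection",
    "multiplicative_check",
    "cutoff_sweep",
    "SubstitutionEffectModel",
    "SubstitutionEffectResults",
]

#: Structural-region code mapping (interface location -> core/noncore).
DEFAULT_REGION_MAP = {
    "COR": "core",
    "RIM": "noncore",
    "SUP": "noncore",
    "INT": "noncore",
    "SUR": "noncore",
}

DEFAULT_CUTOFF = 3.2  # kcal/mol
DEFAULT_CORE_WEIGHT = 0.15

_MUTATION = re.compile(r"^([A-Z])(\d+)([A-Z])$")

_REQUIRED_COLUMNS = ("complex_id", "mutation", "region_code", "kd_wt", "kd_mut")


@dataclass(frozen=True)
class DdgRecord:
    """One mutational binding measurement."""

    complex_id: str
    region: str  # "core" | "noncore"
    receptor_class: str  # "IG" | "TR"
    kd_wt: float
    kd_mut: float
    abs_ddg: float  # kcal/mol
    n_substitutions: int
    substitutions: tuple[tuple[str, int, str], ...]
    mutation: str


@dataclass
class ParsedDdg:
    """Single- and multi-substitution records plus parse diagnostics."""

    singles: list[DdgRecord]
    multis: list[DdgRecord]
    n_skipped: int = 0


@dataclass
class WeightedSample:
    """Observations with per-observation weights summing to 1."""

    values: np.ndarray
    weights: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.weights * self.values))

    def sd(self) -> float:
        mu = self.mean()
        return float(math.sqrt(np.sum(self.weights * (self.values - mu) ** 2)))


@dataclass
class ExponentialFit:
    """Maximum-likelihood exponential fit ``k exp(-k x)``; k = 1/mean."""

    rate: float
    mean: float
    sd: float
    n: int
    ks_stat: float  # empirical vs model CDF discrepancy
    ks_p: float


@dataclass
class FitReport:
    """Bootstrap model-selection result for one candidate model."""

    model: str
    params: dict
    rmse_mean: float
    rmse_sd: float
    n_replicates: int
    split: tuple[int, int]
    implied_s: float | None = None
    s_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "n_replicates": self.n_replicates,
            "split": list(self.split),
            "implied_s": self.implied_s,
            "s_ci": list(self.s_ci) if self.s_ci else None,
        }


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return float(v)
    return v


@dataclass
class MultiplicativeCheck:
    """Log-ratio residuals of observed vs multiplicative (s**m) similarity."""

    residual_mean: float
    residual_sd: float
    n: int
    residuals: np.ndarray


# -- parsing ------------------------------------------------------------


def parse_skempi_like(
    source,
    region_map: dict[str, str] | None = None,
    constants: ThermoConstants = STANDARD_THERMO,
) -> ParsedDdg:
    """Parse a SKEMPI-style mutation CSV (or DataFrame).

    Required columns: ``complex_id, mutation, region_code, kd_wt, kd_mut``
    (Kd in molar; scientific notation accepted) plus ``receptor_class``
    (IG/TR). ``mutation`` holds comma-separated ``A10G``-style
    substitutions; rows with one substitution populate ``singles``, rows
    with several populate ``multis``. Rows with unparseable or non-positive
    Kd are skipped with a logged warning; an unknown region code is an
    error.
    """
    if region_map is None:
        region_map = DEFAULT_REGION_MAP
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        try:
            df = pd.read_csv(source, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{source}: empty CSV") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    has_class = "receptor_class" in df.columns

    singles: list[DdgRecord] = []
    multis: list[DdgRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            kd_wt = float(row.kd_wt)
            kd_mut = float(row.kd_mut)
        except (TypeError, ValueError):
            n_skipped += 1
            logger.warning("skipping row with unparseable Kd: %r", row)
            continue
        if not (kd_wt > 0 and kd_mut > 0) or not (
            math.isfinite(kd_wt) and math.isfinite(kd_mut)
        ):
            n_skipped += 1
            logger.warning("skipping row with non-positive Kd: %r", row)
            continue
        code = str(row.region_code).strip().upper()
        if code not in region_map:
            raise FormatError(f"unknown region code {code!r}")
        subs = []
        for part in str(row.mutation).split(","):
            part = part.strip()
            m = _MUTATION.match(part)
            if m is None:
                raise FormatError(f"unparseable mutation token {part!r}")
            subs.append((m.group(1), int(m.group(2)), m.group(3)))
        abs_ddg = abs(-constants.RT * math.log(kd_wt / kd_mut))
        record = DdgRecord(
            complex_id=str(row.complex_id),
            region=region_map[code],
            receptor_class=str(row.receptor_class) if has_class else "IG",
            kd_wt=kd_wt,
            kd_mut=kd_mut,
            abs_ddg=abs_ddg,
            n_substitutions=len(subs),
            substitutions=tuple(subs),
            mutation=str(row.mutation),
        )
        (singles if len(subs) == 1 else multis).append(record)
    return ParsedDdg(singles=singles, multis=multis, n_skipped=n_skipped)


# -- distribution handling ----------------------------------------------


def remove_extremes(
    records: Sequence[DdgRecord], cutoff: float = DEFAULT_CUTOFF
) -> tuple[list[DdgRecord], int]:
    """Drop records with |ddG| strictly above ``cutoff`` (kcal/mol).

    Extreme effects are over-represented in curated mutation databases
    because dramatic substitutions attract targeted experiments; removing
    them counters that ascertainment bias. Returns (kept, n_removed).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    kept = [r for r in records if r.abs_ddg <= cutoff]
    return kept, len(records) - len(kept)


def master_distribution(
    core: Sequence[float],
    noncore: Sequence[float],
    w_core: float = DEFAULT_CORE_WEIGHT,
    w_noncore: float = 1.0 - DEFAULT_CORE_WEIGHT,
) -> WeightedSample:
    """Combine core and noncore |ddG| samples into a weighted mixture.

    The weighted mean is ``w_core*mean(core) + w_noncore*mean(noncore)``,
    reflecting the proportion of core vs noncore residues in CDR3s rather
    than the (ascertainment-driven) record counts per region.
    """
    core = np.asarray(core, dtype=float)
    noncore = np.asarray(noncore, dtype=float)
    if w_core < 0 or w_noncore < 0 or abs(w_core + w_noncore - 1.0) > 1e-9:
        raise ValidationError("weights must be >= 0 and sum to 1")
    if (w_core > 0 and core.size == 0) or (w_noncore > 0 and noncore.size == 0):
        raise ValidationError("empty component with nonzero weight")
    values = np.concatenate([core, noncore])
    weights = np.concatenate(
        [
            np.full(core.size, w_core / core.size if core.size else 0.0),
            np.full(noncore.size, w_noncore / noncore.size if noncore.size else 0.0),
        ]
    )
    return WeightedSample(values=values, weights=weights)


def fit_exponential(values: Sequence[float]) -> ExponentialFit:
    """ML exponential fit; the rate is 1/mean, with a KS goodness summary."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateFitError("need at least 2 values")
    if np.any(values < 0):
        raise ValidationError("exponential fit requires values >= 0")
    if np.ptp(values) == 0:
        raise DegenerateFitError("constant sample cannot be fit by an exponential")
    mean = float(values.mean())
    ks = stats.kstest(values, "expon", args=(0.0, mean))
    return ExponentialFit(
        rate=1.0 / mean,
        mean=mean,
        sd=float(values.std(ddof=1)),
        n=int(values.size),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def compare_distributions(a: Sequence[float], b: Sequence[float]):
    """Two-sided Mann-Whitney U rank-sum test with tie correction.

    Returns ``(U, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need n >= 2")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# -- biophysical property table -----------------------------------------


def load_property_table() -> pd.DataFrame:
    """Bundled table of per-residue biophysical measures.

    Rows are the 20 canonical residues; columns are side-chain molecular
    weight (Da), van der Waals volume (A^3), total and polar accessible
    surface area (A^2), polarizability, a group electronegativity scale,
    hydrogen-bond donor/acceptor counts, positive/negative charge counts,
    and seven mutually low-redundancy hydrophobicity scales
    (Kyte-Doolittle, Hopp-Woods, Eisenberg consensus, Janin, Rose mean
    buried fraction, Engelman GES, Fauchere-Pliska). Values are
    approximate compiled literature scales; analyses use them only through
    standardized differences, never as calibrated physical quantities.
    """
    ref = importlib.resources.files("classdiv").joinpath("data/aa_properties.tsv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", index_col="aa")
    return table


@dataclass
class PropertyPreprocessing:
    """Charge-merged, deduplicated, standardized table plus PCA summary."""

    reduced: pd.DataFrame  # standardized retained columns
    dropped: list[str]
    pcs: pd.DataFrame  # residues x first n PCs
    explained_variance: np.ndarray
    loadings: pd.DataFrame


def property_preprocessing(
    table: pd.DataFrame | None = None,
    r2_threshold: float = 0.85,
    n_components: int = 5,
) -> PropertyPreprocessing:
    """Merge charges, drop near-duplicate scales, standardize, and run PCA.

    Positive and negative charge counts are merged into a single net
    charge (positive minus negative; no residue carries both). For every
    column pair with R^2 >= ``r2_threshold`` only the first member (in
    column order) is retained. Retained columns are z-scored and the first
    ``n_components`` principal components returned with their
    explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    if table is None:
        table = load_property_table()
    table = table.copy()
    if not np.issubdtype(np.asarray(table.to_numpy()).dtype, np.number):
        raise ValidationError("property table must be fully numeric")
    if "charge_pos" in table.columns and "charge_neg" in table.columns:
        table["net_charge"] = table["charge_pos"] - table["charge_neg"]
        table = table.drop(columns=["charge_pos", "charge_neg"])

    corr2 = table.corr() ** 2
    dropped: list[str] = []
    columns = list(table.columns)
    for i, a in enumerate(columns):
        if a in dropped:
            continue
        for b in columns[i + 1 :]:
            if b in dropped:
                continue
            if corr2.loc[a, b] >= r2_threshold:
                dropped.append(b)
    retained = table.drop(columns=dropped)

    standardized = (retained - retained.mean()) / retained.std(ddof=0)
    pca = PCA(n_components=min(n_components, standardized.shape[1]))
    scores = pca.fit_transform(standardized.to_numpy())
    pc_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PropertyPreprocessing(
        reduced=standardized,
        dropped=dropped,
        pcs=pd.DataFrame(scores, index=retained.index, columns=pc_names),
        explained_variance=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(
            pca.components_.T, index=retained.columns, columns=pc_names
        ),
    )


def _substitution_features(
    records: Sequence[DdgRecord], feature_table: pd.DataFrame
) -> np.ndarray:
    """Per-record feature vector: property(to) - property(from)."""
    rows = np.empty((len(records), feature_table.shape[1]))
    values = feature_table.to_numpy()
    index = {aa: i for i, aa in enumerate(feature_table.index)}
    for i, rec in enumerate(records):
        wt, _, mut = rec.substitutions[0]
        rows[i] = values[index[mut]] - values[index[wt]]
    return rows


# -- bootstrap model selection ------------------------------------------


def _region_weights(regions: np.ndarray, w_core: float) -> np.ndarray:
    """Per-observation weights giving the core/noncore mix its target
    weighting regardless of record counts; renormalized if a region is
    absent from the subset."""
    weights = np.empty(regions.size, dtype=float)
    targets = {"core": w_core, "noncore": 1.0 - w_core}
    present = {r: np.count_nonzero(regions == r) for r in targets}
    total = sum(w for r, w in targets.items() if present[r] > 0)
    for region, w in targets.items():
        if present[region]:
            weights[regions == region] = (w / total) / present[region]
    return weights


def _weighted_rmse(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    return float(math.sqrt(np.sum(w * (y - yhat) ** 2)))


def bootstrap_model_selection(
    records: Sequence[DdgRecord],
    models: Sequence[str] = ("mean", "linear_properties", "linear_pcs"),
    n_reps: int = 200,
    split: tuple[int, int] = (2, 1),
    seed: int | None = None,
    core_weight: float = DEFAULT_CORE_WEIGHT,
    stratify: bool = False,
    constants: ThermoConstants = STANDARD_THERMO,
) -> dict[str, FitReport]:
    """Evaluate candidate |ddG| models by bootstrap over 2:1 splits.

    Each replicate fits on a random train fraction (``split[0] / sum(split)``
    of the records, optionally stratified by region) and records RMSE on
    the held-out rest; observations are weighted so core:noncore carries
    the ``core_weight`` mix. The mean model predicts the weighted training
    mean; linear models are OLS on substitution property (or PC)
    differences, falling back to the mean with a warning if the design is
    singular. The mean model's report carries the implied
    ``s = exp(-mean|ddG|/RT)`` with a percentile CI from a standard
    nonparametric bootstrap of the weighted mean.
    """
    records = list(records)
    n = len(records)
    if n < 10:
        raise ValidationError(f"need >= 10 records, got {n}")
    rng = np.random.default_rng(seed)
    y = np.array([r.abs_ddg for r in records])
    regions = np.array([r.region for r in records])
    train_frac = split[0] / (split[0] + split[1])

    features: dict[str, np.ndarray] = {}
    if "linear_properties" in models or "linear_pcs" in models:
        prep = property_preprocessing()
        if "linear_properties" in models:
            features["linear_properties"] = _substitution_features(
                records, prep.reduced
            )
        if "linear_pcs" in models:
            features["linear_pcs"] = _substitution_features(records, prep.pcs)

    rmse: dict[str, list[float]] = {m: [] for m in models}
    train_means: list[float] = []
    coef_sums: dict[str, np.ndarray] = {}
    for _ in range(n_reps):
        if stratify:
            train_idx: list[int] = []
            for region in ("core", "noncore"):
                idx = np.flatnonzero(regions == region)
                perm = rng.permutation(idx)
                train_idx.extend(perm[: round(train_frac * idx.size)])
            train_mask = np.zeros(n, dtype=bool)
            train_mask[train_idx] = True
        else:
            perm = rng.permutation(n)
            train_mask = np.zeros(n, dtype=bool)
            train_mask[perm[: round(train_frac * n)]] = True
        test_mask = ~train_mask
        w_train = _region_weights(regions[train_mask], core_weight)
        w_test = _region_weights(regions[test_mask], core_weight)
        y_train, y_test = y[train_mask], y[test_mask]

        mu = float(np.sum(w_train * y_train))
        train_means.append(mu)
        if "mean" in models:
            rmse["mean"].append(_weighted_rmse(y_test, mu, w_test))
        for name, X in features.items():
            X_train = np.column_stack(
                [np.ones(y_train.size), X[train_mask]]
            ) * np.sqrt(w_train)[:, None]
            b_train = y_train * np.sqrt(w_train)
            coef, _, rank, _ = np.linalg.lstsq(X_train, b_train, rcond=None)
            if rank < X_train.shape[1]:
                logger.warning(
                    "singular design for %s; replicate falls back to mean model",
                    name,
                )
                yhat = np.full(y_test.size, mu)
            else:
                yhat = np.column_stack([np.ones(y_test.size), X[test_mask]]) @ coef
                coef_sums[name] = coef_sums.get(name, 0) + coef
            rmse[name].append(_weighted_rmse(y_test, yhat, w_test))

    # Nonparametric bootstrap (resample n with replacement) for the CI of
    # the weighted mean and the implied s.
    boot_means = np.empty(n_reps)
    for b in range(n_reps):
        idx = rng.integers(0, n, size=n)
        boot_means[b] = np.sum(_region_weights(regions[idx], core_weight) * y[idx])
    s_lo, s_hi = np.exp(-np.percentile(boot_means, [97.5, 2.5]) / constants.RT)

    full_mean = float(np.sum(_region_weights(regions, core_weight) * y))
    reports: dict[str, FitReport] = {}
    for name in models:
        arr = np.asarray(rmse[name])
        params: dict = {}
        implied_s = s_ci = None
        if name == "mean":
            params = {
                "mean_ddg": full_mean,
                "train_mean_ddg_mean": float(np.mean(train_means)),
                "train_mean_ddg_sd": float(np.std(train_means, ddof=1))
                if n_reps > 1
                else 0.0,
            }
            implied_s = float(math.exp(-full_mean / constants.RT))
            s_ci = (float(s_lo), float(s_hi))
        elif name in coef_sums:
            params = {"mean_coef": coef_sums[name] / n_reps}
        reports[name] = FitReport(
            model=name,
            params=params,
            rmse_mean=float(arr.mean()),
            rmse_sd=float(arr.std(ddof=1)) if n_reps > 1 else 0.0,
            n_replicates=n_reps,
            split=tuple(split),
            implied_s=implied_s,
            s_ci=s_ci,
        )
    return reports


def cutoff_sweep(
    records: Sequence[DdgRecord],
    cutoffs: Sequence[float] = (3.0, 3.1, 3.2, 3.3, 3.4),
    n_reps: int = 50,
    seed: int | None = None,
    core_weight: float = DEFAULT_CORE_WEIGHT,
    constants: ThermoConstants = STANDARD_THERMO,
) -> pd.DataFrame:
    """Sensitivity of the mean-model fit to the extreme-value cutoff."""
    rows = []
    for cutoff in cutoffs:
        kept, n_removed = remove_extremes(records, cutoff)
        report = bootstrap_model_selection(
            kept,
            models=("mean",),
            n_reps=n_reps,
            seed=seed,
            core_weight=core_weight,
            constants=constants,
        )["mean"]
        rows.append(
            {
                "cutoff": cutoff,
                "n_used": len(kept),
                "n_removed": n_removed,
                "implied_s": report.implied_s,
                "rmse_mean": report.rmse_mean,
                "rmse_sd": report.rmse_sd,
            }
        )
    return pd.DataFrame(rows)


def multiplicative_check(
    multi_records: Sequence[DdgRecord],
    s: float,
    constants: ThermoConstants = STANDARD_THERMO,
) -> MultiplicativeCheck:
    """Test the multiplicative kernel against multi-substitution records.

    For a record with m substitutions the kernel predicts similarity
    ``s**m``; the observed similarity is ``exp(-|ddG|/RT)``. Residuals are
    the log-ratio ``ln(observed) - m ln(s)``; a mean near 0 supports
    multiplicative independence, a systematically negative mean indicates
    sub-multiplicative binding effects.
    """
    multi_records = [r for r in multi_records if r.n_substitutions >= 2]
    if not multi_records:
        raise ValidationError("no records with n_substitutions >= 2")
    residuals = np.array(
        [
            -r.abs_ddg / constants.RT - r.n_substitutions * math.log(s)
            for r in multi_records
        ]
    )
    return MultiplicativeCheck(
        residual_mean=float(residuals.mean()),
        residual_sd=float(residuals.std(ddof=1)) if residuals.size > 1 else 0.0,
        n=residuals.size,
        residuals=residuals,
    )


# -- Model / Results interface ------------------------------------------


class SubstitutionEffectModel:
    """Single-substitution |ddG| model-selection pipeline.

    Build from parsed records (or a CSV/DataFrame in the SKEMPI-like
    dialect), then :meth:`fit` to run extreme-value removal and bootstrap
    model selection.
    """

    def __init__(
        self,
        singles: Sequence[DdgRecord],
        multis: Sequence[DdgRecord] = (),
        cutoff: float = DEFAULT_CUTOFF,
        core_weight: float = DEFAULT_CORE_WEIGHT,
        constants: ThermoConstants = STANDARD_THERMO,
    ) -> None:
        self.singles = list(singles)
        self.multis = list(multis)
        self.cutoff = cutoff
        self.core_weight = core_weight
        self.constants = constants

    @classmethod
    def from_csv(cls, path, region_map: dict[str, str] | None = None, **kwargs):
        parsed = parse_skempi_like(path, region_map=region_map)
        return cls(parsed.singles, parsed.multis, **kwargs)

    from_dataframe = from_csv  # parse_skempi_like accepts both

    def master(self) -> WeightedSample:
        """Weighted core/noncore master |ddG| sample after cutoff removal."""
        kept, _ = remove_extremes(self.singles, self.cutoff)
        core = [r.abs_ddg for r in kept if r.region == "core"]
        noncore = [r.abs_ddg for r in kept if r.region == "noncore"]
        return master_distribution(
            core, noncore, self.core_weight, 1.0 - self.core_weight
        )

    def fit(
        self,
        models: Sequence[str] = ("mean", "linear_properties", "linear_pcs"),
        n_reps: int = 200,
        seed: int | None = None,
        stratify: bool = False,
    ) -> "SubstitutionEffectResults":
        kept, n_removed = remove_extremes(self.singles, self.cutoff)
        reports = bootstrap_model_selection(
            kept,
            models=models,
            n_reps=n_reps,
            seed=seed,
            core_weight=self.core_weight,
            stratify=stratify,
            constants=self.constants,
        )
        return SubstitutionEffectResults(
            model=self,
            reports=reports,
            n_used=len(kept),
            n_removed=n_removed,
        )


class SubstitutionEffectResults:
    """Fit results: per-model reports, the selected model, and implied s."""

    def __init__(
        self,
        model: SubstitutionEffectModel,
        reports: dict[str, FitReport],
        n_used: int,
        n_removed: int,
    ) -> None:
        self.model = model
        self.reports = reports
        self.n_used = n_used
        self.n_removed = n_removed
        self.selected = self._select()

    def _select(self) -> str:
        # Prefer the mean model unless a competitor's held-out RMSE is
        # better by more than 2 SD (simplicity on statistical ties).
        if "mean" not in self.reports:
            return min(self.reports, key=lambda m: self.reports[m].rmse_mean)
        mean_report = self.reports["mean"]
        best = "mean"
        for name, report in self.reports.items():
            if name == "mean":
                continue
            if report.rmse_mean < mean_report.rmse_mean - 2.0 * report.rmse_sd:
                if report.rmse_mean < self.reports[best].rmse_mean:
                    best = name
        return best

    @property
    def s(self) -> float | None:
        report = self.reports.get("mean")
        return None if report is None else report.implied_s

    @property
    def s_ci(self) -> tuple[float, float] | None:
        report = self.reports.get("mean")
        return None if report is None else report.s_ci

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_removed": self.n_removed,
            "cutoff": self.model.cutoff,
            "core_weight": self.model.core_weight,
            "selected": self.selected,
            "implied_s": self.s,
            "s_ci": list(self.s_ci) if self.s_ci else None,
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
        }

    def summary(self) -> str:
        lines = [
            "Substitution-effect model selection",
            "===================================",
            f"records used: {self.n_used}  (removed beyond "
            f"{self.model.cutoff} kcal/mol: {self.n_removed})",
            f"core weight: {self.model.core_weight:.2f}",
            "",
            f"{'model':<20}{'RMSE (kcal/mol)':<22}{'implied s':<12}{'95% CI'}",
            "-" * 68,
        ]
        for name, r in self.reports.items():
            rmse = f"{r.rmse_mean:.3f} +/- {r.rmse_sd:.3f}"
            s_txt = f"{r.implied_s:.3f}" if r.implied_s is not None else "-"
            ci_txt = (
                f"({r.s_ci[0]:.3f}, {r.s_ci[1]:.3f})" if r.s_ci is not None else "-"
            )
            lines.append(f"{name:<20}{rmse:<22}{s_txt:<12}{ci_txt}")
        lines += ["-" * 68, f"selected: {self.selected}"]
        return "\n".join(lines)
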