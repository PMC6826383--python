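"""Exhaustive prognostic screening of particle filter subsets.

The discovery engine: enumerate the filter grid (binarization x circularity
x size), measure every image once per binarization, aggregate each filtered
subset to per-patient features, and score every (subset, feature) pair with
an optimism-corrected AUC and a Cox model on the optimal-cutpoint
dichotomization.  Records are ranked by ``|corrected AUC - 0.5|`` so
low-risk features (AUC < 0.5) compete on equal terms.

The default grid is 4 binarizations (auto, 220, 240, 250) x 5 circularity
minima (0, 0.2, 0.4, 0.6, 0.8) x 4 size minima (10, 20, 50, 100 px) = 80
subsets, each scored on 5 features = 400 records.

Organized in the model/results style: build a :class:`SubsetScreen` from a
cohort table plus images, call :meth:`~SubsetScreen.fit`, inspect the
returned :class:`ScreenResults` (``summary()``, ``records``, ``to_csv``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .features import FEATURE_NAMES, ImageFeatures, patient_features
from .imaging import GrayImage, binarize, read_image
from .particles import PERIMETER_ESTIMATOR, FilterSpec, measure_mask
from .survstats import (
    AUCResult,
    CoxResult,
    auc_with_optimism,
    cox_fit,
    optimal_cutpoint,
)

__all__ = [
    "DEFAULT_BINARIZATIONS",
    "DEFAULT_CIRCULARITY_MINS",
    "DEFAULT_SIZE_MINS",
    "enumerate_grid",
    "SubsetEvaluation",
    "SizeProfile",
    "SubsetScreen",
    "ScreenResults",
]

DEFAULT_BINARIZATIONS = ("auto", 220, 240, 250)
DEFAULT_CIRCULARITY_MINS = (0.0, 0.2, 0.4, 0.6, 0.8)
DEFAULT_SIZE_MINS = (10, 20, 50, 100)


def enumerate_grid(
    binarizations=DEFAULT_BINARIZATIONS,
    circularity_mins=DEFAULT_CIRCULARITY_MINS,
    size_mins=DEFAULT_SIZE_MINS,
) -> list[FilterSpec]:
    """Full Cartesian product of the three filter axes.

    Order is binarization-major, then circularity, then size; the default
    axes yield exactly 80 specs.
    """
    if not binarizations or not circularity_mins or not size_mins:
        raise ValueError("every grid axis must be non-empty")
    return [
        FilterSpec(binarization=b, circularity_min=c, size_min_px=s)
        for b, c, s in itertools.product(binarizations, circularity_mins, size_mins)
    ]


@dataclass(frozen=True)
class SubsetEvaluation:
    """Prognostic scorecard of one feature under one filter subset."""

    spec: FilterSpec
    feature: str
    auc: AUCResult
    cox: CoxResult | None
    cutpoint: float | None
    n_patients: int
    n_missing: int
    flagged: bool  # feature missing for > 50% of patients -> excluded from ranking
    note: str = ""


@dataclass(frozen=True)
class SizeProfile:
    """AUC of the count feature as a function of the particle-size window."""

    windows: tuple[tuple[float, float], ...]
    auc: tuple[float, ...]       # NaN when the window is empty cohort-wide
    tally: tuple[int, ...]       # particles cohort-wide per window

    def argmax_window(self) -> tuple[float, float]:
        vals = np.asarray(self.auc)
        if np.isnan(vals).all():
            raise ValueError("profile has no populated window")
        return self.windows[int(np.nanargmax(np.abs(vals - 0.5)))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                size_lo=[w[0] for w in self.windows],
                size_hi=[w[1] for w in self.windows],
                auc=self.auc,
                tally=self.tally,
            )
        )

    def plot(self, ax=None):
        """Bar plot of the count-feature AUC per particle-size window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        labels = [f"{lo:g}-{hi:g}" for lo, hi in self.windows]
        ax.bar(range(len(labels)), self.auc, color="#4878a8")
        ax.axhline(0.5, color="0.4", lw=0.8, ls="--")
        ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
        ax.set_xlabel("particle size window (px)")
        ax.set_ylabel("count AUC")
        ax.set_ylim(0, 1)
        for i, t in enumerate(self.tally):
            ax.annotate(str(t), (i, 0.03), ha="center", fontsize=8, color="w")
        return ax


class SubsetScreen:
    """Screening model over a patient cohort with images.

    Parameters
    ----------
    cohort : DataFrame
        One row per patient with columns ``patient_id``, ``time_months``,
        ``event`` (plus optional covariates, carried through).
    images : dict
        ``patient_id -> list of GrayImage`` (>= 1 per patient).
    grid : list of FilterSpec, optional
        Defaults to the standard 80-subset grid.
    connectivity : {4, 8}
        Particle connectivity (default 8).
    min_group_fraction : float
        Admissibility bound for the optimal-cutpoint search (default 0.10).
    bootstrap_B : int
        Resamples for the AUC optimism correction (default 1000).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        images: dict[str, list[GrayImage]],
        grid: list[FilterSpec] | None = None,
        connectivity: int = 8,
        min_group_fraction: float = 0.10,
        bootstrap_B: int = 1000,
    ):
        cohort = pd.DataFrame(cohort).copy()
        required = {"patient_id", "time_months", "event"}
        if not required.issubset(cohort.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if cohort["event"].nunique() < 2:
            raise ValueError("cohort must contain both outcome classes")
        missing = [p for p in cohort["patient_id"] if not images.get(p)]
        if missing:
            raise ValueError(f"patients without images: {missing[:5]}")
        # canonical patient order makes every downstream step order-invariant
        self.cohort = cohort.sort_values("patient_id").reset_index(drop=True)
        self.images = images
        self.grid = list(grid) if grid is not None else enumerate_grid()
        self.connectivity = connectivity
        self.min_group_fraction = min_group_fraction
        self.bootstrap_B = bootstrap_B
        self._cache: dict[object, dict[str, list[dict[str, np.ndarray]]]] = {}
        self._mask_cache: dict[tuple, dict[str, np.ndarray]] = {}

    @classmethod
    def from_csv(cls, csv_path, pixel_size_um: float = 1.4, **kwargs) -> "SubsetScreen":
        """Build from a cohort CSV with an ``image_paths`` column
        (semicolon-separated paths to PNG/TIFF files)."""
        cohort = pd.read_csv(csv_path)
        images = {
            row["patient_id"]: [
                read_image(p, pixel_size_um) for p in str(row["image_paths"]).split(";")
            ]
            for _, row in cohort.iterrows()
        }
        return cls(cohort.drop(columns=["image_paths"]), images, **kwargs)

    # -- measurement cache --------------------------------------------------

    def _measurements(self, binarization) -> dict[str, list[dict[str, np.ndarray]]]:
        """Per-image particle measurement arrays for one binarization setting.

        Measured once and cached; the 5 x 4 circularity/size filters of each
        binarization reuse these arrays (measure once, filter many).  A
        second content-keyed cache recognises when two binarization settings
        produce the same mask for an image (common when the intensity
        histogram has an empty band spanning several thresholds) and reuses
        the measurements.
        """
        if binarization in self._cache:
            return self._cache[binarization]
        out: dict[str, list[dict[str, np.ndarray]]] = {}
        for pid in self.cohort["patient_id"]:
            per_image = []
            for j, img in enumerate(self.images[pid]):
                mask = binarize(img, binarization)
                key = (pid, j, mask.data.tobytes())
                hit = self._mask_cache.get(key)
                if hit is None:
                    parts = measure_mask(
                        mask, connectivity=self.connectivity, with_feret=False
                    )
                    hit = dict(
                        area=np.array([p.area_px for p in parts], float),
                        circ=np.array([p.circularity for p in parts], float),
                        sol=np.array([p.solidity for p in parts], float),
                    )
                    self._mask_cache[key] = hit
                per_image.append(hit)
            out[pid] = per_image
        self._cache[binarization] = out
        return out

    def patient_feature_matrix(self, spec: FilterSpec) -> pd.DataFrame:
        """Per-patient feature vectors under one filter subset."""
        meas = self._measurements(spec.binarization)
        rows = []
        for pid in self.cohort["patient_id"]:
            feats = []
            for m in meas[pid]:
                keep = (
                    (m["circ"] >= spec.circularity_min)
                    & (m["circ"] <= spec.circularity_max)
                    & (m["area"] >= spec.size_min_px)
                    & (m["area"] <= spec.size_max_px)
                )
                n = int(keep.sum())
                if n == 0:
                    feats.append(ImageFeatures(0, 0.0, 0.0, math.nan, math.nan))
                else:
                    total = float(m["area"][keep].sum())
                    feats.append(
                        ImageFeatures(
                            n, total, total / n,
                            float(m["circ"][keep].mean()),
                            float(m["sol"][keep].mean()),
                        )
                    )
            rows.append(patient_features(feats))
        df = pd.DataFrame(rows)
        df.insert(0, "patient_id", self.cohort["patient_id"].to_numpy())
        return df

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0) -> "ScreenResults":
        """Evaluate every (subset, feature) record and rank them.

        Per record: optimism-corrected AUC on the continuous feature values
        and a univariate Cox model on the optimal-cutpoint dichotomization.
        Each record draws its bootstrap stream from ``(seed, record index)``,
        so results do not depend on patient order or evaluation order.
        """
        time = self.cohort["time_months"].to_numpy(float)
        event = self.cohort["event"].to_numpy(int)
        n = len(self.cohort)
        records: list[SubsetEvaluation] = []
        for i_spec, spec in enumerate(self.grid):
            fm = self.patient_feature_matrix(spec)
            for i_feat, feat in enumerate(FEATURE_NAMES):
                vals = fm[feat].to_numpy(float)
                ok = ~np.isnan(vals)
                n_missing = int((~ok).sum())
                flagged = n_missing > 0.5 * n
                rec_rng = np.random.default_rng([seed, i_spec, i_feat])
                note = ""
                auc = cox = cut = None
                if not flagged and event[ok].sum() > 0 and (1 - event[ok]).sum() > 0:
                    try:
                        auc = auc_with_optimism(
                            vals[ok], event[ok], B=self.bootstrap_B, seed=rec_rng
                        )
                    except ValueError as exc:
                        note = f"auc: {exc}"
                        flagged = True
                    if auc is not None:
                        try:
                            cut = optimal_cutpoint(
                                vals[ok], time[ok], event[ok], self.min_group_fraction
                            )
                            high = pd.DataFrame({feat + "_high": (vals[ok] > cut).astype(float)})
                            cox = cox_fit(high, time[ok], event[ok])
                            cox = CoxResult(
                                names=cox.names, coef=cox.coef, se=cox.se, hr=cox.hr,
                                hr_ci95=cox.hr_ci95, p_values=cox.p_values, n=cox.n,
                                n_events=cox.n_events, cutpoint=cut, ties=cox.ties,
                            )
                        except (ValueError, RuntimeError) as exc:
                            note = f"cox: {exc}"
                else:
                    flagged = True
                    note = note or f"feature missing for {n_missing}/{n} patients"
                records.append(
                    SubsetEvaluation(
                        spec=spec, feature=feat, auc=auc, cox=cox, cutpoint=cut,
                        n_patients=n - n_missing, n_missing=n_missing,
                        flagged=flagged, note=note,
                    )
                )
        return ScreenResults(self, records, seed)

    # -- size profile ---------------------------------------------------------

    def size_profile(
        self,
        windows: list[tuple[float, float]],
        binarization=250,
        circularity_min: float = 0.8,
        circularity_max: float = 1.0,
    ) -> SizeProfile:
        """AUC of the per-patient count within each particle-size window.

        Windows are half-open ``[lo, hi)``, must be non-overlapping and
        ascending.  A window holding no particles cohort-wide gets a missing
        AUC and tally 0.
        """
        if len(windows) < 2:
            raise ValueError("size_profile requires >= 2 windows")
        for (l0, h0), (l1, h1) in zip(windows, windows[1:]):
            if not (l0 < h0 and l1 < h1 and h0 <= l1):
                raise ValueError("windows must be ascending and non-overlapping")
        meas = self._measurements(binarization)
        event = self.cohort["event"].to_numpy(int)
        aucs, tallies = [], []
        for lo, hi in windows:
            per_patient = []
            tally = 0
            for pid in self.cohort["patient_id"]:
                cnt = []
                for m in meas[pid]:
                    keep = (
                        (m["circ"] >= circularity_min)
                        & (m["circ"] <= circularity_max)
                        & (m["area"] >= lo)
                        & (m["area"] < hi)
                    )
                    cnt.append(int(keep.sum()))
                tally += int(np.sum(cnt))
                per_patient.append(float(np.mean(cnt)))
            if tally == 0:
                aucs.append(math.nan)
            else:
                from .survstats import auc_mann_whitney

                aucs.append(auc_mann_whitney(per_patient, event).auc)
            tallies.append(tally)
        return SizeProfile(tuple(windows), tuple(aucs), tuple(tallies))


class ScreenResults:
    """Ranked screening records with export helpers."""

    def __init__(self, model: SubsetScreen, records: list[SubsetEvaluation], seed: int):
        self.model = model
        self.seed = seed
        self.records = records
        evaluable = [r for r in records if not r.flagged and r.auc is not None]
        self.ranked = sorted(
            evaluable,
            key=lambda r: (
                -abs(r.auc.corrected_auc - 0.5),
                r.spec.label,
                r.feature,
            ),
        )
        self.n_flagged = len(records) - len(evaluable)

    @property
    def top(self) -> SubsetEvaluation:
        if not self.ranked:
            raise ValueError("no evaluable records")
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        """Full record table (mirrors the per-subset scorecard columns)."""
        n_tests = max(1, len([r for r in self.records if not r.flagged]))
        rows = []
        for r in self.records:
            a = r.auc
            c = r.cox
            rows.append(
                dict(
                    binarization=r.spec.binarization,
                    circularity_min=r.spec.circularity_min,
                    size_min_px=r.spec.size_min_px,
                    feature=r.feature,
                    auc=a.auc if a else math.nan,
                    auc_lo=a.ci95[0] if a else math.nan,
                    auc_hi=a.ci95[1] if a else math.nan,
                    auc_p=a.p_value if a else math.nan,
                    corrected_auc=a.corrected_auc if a else math.nan,
                    cutpoint=r.cutpoint if r.cutpoint is not None else math.nan,
                    hr=c.hr[0] if c is not None else math.nan,
                    hr_lo=c.hr_ci95[0, 0] if c is not None else math.nan,
                    hr_hi=c.hr_ci95[0, 1] if c is not None else math.nan,
                    hr_p=c.p_values[0] if c is not None else math.nan,
                    n_patients=r.n_patients,
                    flagged=r.flagged,
                    bonferroni_significant=(
                        bool(a.p_value < 0.05 / n_tests) if a else False
                    ),
                    note=r.note,
                )
            )
        return pd.DataFrame(rows)

    def summary(self, n: int = 10) -> pd.DataFrame:
        """The top-n ranked records by |corrected AUC - 0.5|."""
        df = self.to_frame()
        df = df[~df["flagged"]]
        df = df.reindex(
            df["corrected_auc"].sub(0.5).abs().sort_values(ascending=False).index
        )
        return df.head(n).reset_index(drop=True)

    def manifest(self) -> dict:
        return dict(
            package_version=_pkg_version,
            seed=self.seed,
            bootstrap_B=self.model.bootstrap_B,
            n_patients=len(self.model.cohort),
            n_specs=len(self.model.grid),
            n_records=len(self.records),
            n_flagged=self.n_flagged,
            connectivity=self.model.connectivity,
            min_group_fraction=self.model.min_group_fraction,
            perimeter_estimator=PERIMETER_ESTIMATOR,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_auc_by_circularity(self, feature: str = "count", ax=None):
        """Corrected AUC of one feature vs circularity threshold, one line
        per binarization (at the smallest size minimum in the grid)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        df = self.to_frame()
        df = df[(df.feature == feature) & ~df.flagged]
        if df.empty:
            raise ValueError(f"no evaluable records for feature {feature!r}")
        df = df[df.size_min_px == df.size_min_px.min()]
        for b, grp in df.groupby("binarization"):
            grp = grp.sort_values("circularity_min")
            ax.plot(grp.circularity_min, grp.corrected_auc, marker="o", label=str(b))
        ax.axhline(0.5, color="0.4", lw=0.8, ls="--")
        ax.set_xlabel("circularity threshold")
        ax.set_ylabel(f"corrected AUC ({feature})")
        ax.set_ylim(0, 1)
        ax.legend(title="binarization", fontsize=8)
        return ax
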