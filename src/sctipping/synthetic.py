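"""Synthetic SCBC-like snapshot series with planted low-rank structure.

The generator emulates a 4-day time course of single-cell proteomic/metabolic
snapshots from a drug-treated melanoma line: log-levels decompose into a
per-analyte steady state ``g0`` plus a time-dependent module (``lambda1 * g1``,
monotone schedule crossing zero between the intermediate days) and a
bifurcating, path-dependent module (``lambda2 * g2``, sign set by a per-cell
lineage path label — MITF-high cells carry negative scores by convention).
Designated "tipping" cells at an intermediate day additionally share a latent
fluctuation factor ``f_c * h`` which raises analyte-analyte correlation and
cell-to-cell heterogeneity, the statistical signature of a critical
transition.  Measurement noise is i.i.d. Gaussian in log space (log-normal in
linear space).

The generator is the study-condition definition for the whole test suite:
its defaults, together with ground-truth labels, drive the parameter-recovery
and tipping-detection simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_CATEGORIES,
    DEFAULT_DAYS,
    AnalytePanel,
    SingleCellTable,
    ValidationError,
)
from .cluster import ClusterAssignment

#: Default per-day cell counts (the scale of a realistic SCBC run).
DEFAULT_N_PER_DAY = (156, 185, 162, 171)

_PANEL_NAMES = tuple(DEFAULT_CATEGORIES)

# Raw (un-normalized) module loadings, keyed by analyte.  g1 is the
# time-dependent module: proliferation/oncogenic-signaling markers fall under
# treatment while resistance markers rise.  g2 is the path module: positive
# scores mark the MITF-low (lower, invasive-like) path, so melanocytic
# markers load negatively and mesenchymal/resistance markers positively.
_G1_RAW = {
    "Ki67": -0.9, "p-ERK": -0.6, "p-S6": -0.5, "p-mTOR": -0.4,
    "GlucoseUptake": -0.3, "HIF1a": -0.3, "PKM2": -0.2, "LDH": -0.2,
    "PFK": -0.2, "MART1": -0.1,
    "NGFR": 0.7, "AXL": 0.7, "N-cadherin": 0.6, "TNFR": 0.5, "Slug": 0.4,
    "p-NFkB-p65": 0.3, "p-AMPKa": 0.3, "p-LKB": 0.2, "p-ACAC": 0.2,
}
_G2_RAW = {
    "MITF": -0.9, "MART1": -0.8, "Ki67": -0.5, "PFK": -0.4, "Slug": -0.35,
    "NGFR": 0.4, "AXL": 0.4, "p-NFkB-p65": 0.35, "N-cadherin": 0.35,
    "TNFR": 0.3,
}

# Latent tipping-factor loadings: uniform weight over the subnetwork each
# near-critical state engages — the path's hub analytes plus the
# co-fluctuating lineage (upper) or stress (lower) axis.  Both factors have
# support inside the 10-marker clustering/criticality subset.
_H_HIGH_RAW = {
    "MITF": 1.0, "PFK": 1.0, "PKM2": 1.0, "LDH": 1.0, "p-LKB": 1.0,
    "Slug": 1.0, "MART1": 1.0, "Ki67": 1.0,
}
_H_LOW_RAW = {
    "TNFR": 1.0, "N-cadherin": 1.0, "p-NFkB-p65": 1.0,
    "HIF1a": 1.0, "p-ERK": 1.0, "p-AMPKa": 1.0, "p-ACAC": 1.0,
}


def default_panel() -> AnalytePanel:
    """The default 20-analyte panel across six functional categories."""
    return AnalytePanel(names=_PANEL_NAMES, category=dict(DEFAULT_CATEGORIES))


def _vector(raw: dict[str, float], names: tuple[str, ...]) -> np.ndarray:
    return np.array([raw.get(n, 0.0) for n in names])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def default_loadings(names: tuple[str, ...] = _PANEL_NAMES):
    """Steady state plus orthonormal module / tipping loadings.

    ``g1`` and ``g2`` are orthogonalized against the steady-state direction
    (and each other) so the planted modules sit in the deviation subspace,
    as surprisal constraints do.
    """
    n = len(names)
    g0 = np.linspace(5.0, 8.0, n)
    e0 = _unit(g0)
    g1 = _vector(_G1_RAW, names)
    g1 = _unit(g1 - (g1 @ e0) * e0)
    g2 = _vector(_G2_RAW, names)
    g2 = g2 - (g2 @ e0) * e0
    g2 = _unit(g2 - (g2 @ g1) * g1)
    h_high = _unit(_vector(_H_HIGH_RAW, names))
    h_low = _unit(_vector(_H_LOW_RAW, names))
    return g0, g1, g2, h_high, h_low


@dataclass(frozen=True)
class TippingSpec:
    """Planted tipping cluster for one path: at ``day``, a ``fraction`` of
    the path's cells share a latent factor ``loading`` with per-cell weight
    drawn from ``Normal(0, latent_sd)``."""

    day: int = 3
    fraction: float = 0.6
    latent_sd: float = 0.8
    loading: np.ndarray | None = None  # defaults to the path's hub factor

    def validate(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValidationError("tipping fraction must be in (0, 1]")
        if self.latent_sd <= 0:
            raise ValidationError("tipping latent_sd must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    n_cells_per_day: tuple[int, ...] = DEFAULT_N_PER_DAY
    days: tuple[int, ...] = DEFAULT_DAYS
    n_analytes: int = 20
    g0: np.ndarray | None = None
    g1: np.ndarray | None = None
    g2: np.ndarray | None = None
    lambda1_schedule: tuple[float, ...] = (-1.0, -0.4, 0.4, 1.0)
    lambda2_magnitude: float = 0.7
    p_high: float = 0.5
    noise_sd: float = 0.1
    #: jitter of per-cell scores around the day/path mean, as a fraction of
    #: the schedule range (module 1) or of the magnitude (module 2)
    lambda1_jitter_frac: float = 0.1
    lambda2_jitter_frac: float = 0.1
    tipping: dict | None = None  # {"high": TippingSpec, "low": TippingSpec}
    seed: int = 0

    def resolved(self) -> "GeneratorConfig":
        """Fill in default loadings/tipping and validate invariants."""
        g0d, g1d, g2d, h_high, h_low = default_loadings(_PANEL_NAMES)
        if self.n_analytes != 20:
            # generic low-rank structure for non-default panel sizes
            rng = np.random.default_rng(12345)
            g0d = np.linspace(5.0, 8.0, self.n_analytes)
            e0 = _unit(g0d)
            g1d = rng.normal(size=self.n_analytes)
            g1d = _unit(g1d - (g1d @ e0) * e0)
            g2d = rng.normal(size=self.n_analytes)
            g2d = g2d - (g2d @ e0) * e0
            g2d = _unit(g2d - (g2d @ g1d) * g1d)
            h_high = _unit(rng.normal(size=self.n_analytes))
            h_low = _unit(rng.normal(size=self.n_analytes))
        g0 = g0d if self.g0 is None else np.asarray(self.g0, float)
        g1 = g1d if self.g1 is None else np.asarray(self.g1, float)
        g2 = g2d if self.g2 is None else np.asarray(self.g2, float)
        tipping = self.tipping
        if tipping is None:
            tipping = {
                "high": TippingSpec(loading=h_high),
                "low": TippingSpec(loading=h_low),
            }
        else:
            tipping = dict(tipping)
            for path, default_h in (("high", h_high), ("low", h_low)):
                spec = tipping.get(path)
                if spec is not None and spec.loading is None:
                    tipping[path] = replace(spec, loading=default_h)
        cfg = replace(self, g0=g0, g1=g1, g2=g2, tipping=tipping)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.n_cells_per_day) != len(self.days):
            raise ValidationError("one cell count per day required")
        if any(n <= 0 for n in self.n_cells_per_day):
            raise ValidationError("cell counts must be positive")
        if len(self.lambda1_schedule) != len(self.days):
            raise ValidationError("lambda1_schedule needs one value per day")
        sched = np.asarray(self.lambda1_schedule, float)
        if not np.all(np.diff(sched) > 0):
            raise ValidationError("lambda1_schedule must be strictly increasing")
        if np.sum(np.diff(np.sign(sched)) != 0) != 1 or sched[0] >= 0 or sched[-1] <= 0:
            raise ValidationError("lambda1_schedule must change sign exactly once")
        if not 0.0 < self.p_high < 1.0:
            raise ValidationError("p_high must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.lambda2_magnitude <= 0:
            raise ValidationError("lambda2_magnitude must be positive")
        for g, name in ((self.g1, "g1"), (self.g2, "g2")):
            if g is not None and abs(np.linalg.norm(g) - 1.0) > 1e-8:
                raise ValidationError(f"{name} must be unit norm")
        if self.g1 is not None and self.g2 is not None:
            if abs(float(self.g1 @ self.g2)) > 1e-8:
                raise ValidationError("g1 and g2 must be orthogonal")
        if self.tipping is not None:
            for path, spec in self.tipping.items():
                if path not in ("high", "low"):
                    raise ValidationError(f"unknown tipping path {path!r}")
                spec.validate()
                if spec.day not in self.days:
                    raise ValidationError(
                        f"tipping day {spec.day} not in days {self.days}"
                    )


@dataclass
class GroundTruth:
    """Per-cell planted labels and scores plus the loading vectors."""

    frame: pd.DataFrame  # cell_id, day, path, lambda1, lambda2, tipping
    loadings: dict[str, np.ndarray]  # g0, g1, g2, h_high, h_low

    @property
    def path(self) -> np.ndarray:
        return self.frame["path"].to_numpy()

    @property
    def lambda1(self) -> np.ndarray:
        return self.frame["lambda1"].to_numpy()

    @property
    def lambda2(self) -> np.ndarray:
        return self.frame["lambda2"].to_numpy()

    @property
    def tipping(self) -> np.ndarray:
        return self.frame["tipping"].to_numpy()


def generate(config: GeneratorConfig) -> tuple[SingleCellTable, GroundTruth]:
    """Draw one snapshot series; identical config and seed give identical
    output bit for bit.  The table is returned in linear space."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_analytes == 20:
        panel = default_panel()
    else:
        panel = AnalytePanel.from_names(
            [f"analyte{i}" for i in range(cfg.n_analytes)],
            default_category="signaling phosphoprotein",
        )
    sched = np.asarray(cfg.lambda1_schedule, float)
    jitter1 = cfg.lambda1_jitter_frac * (sched.max() - sched.min())
    jitter2 = cfg.lambda2_jitter_frac * cfg.lambda2_magnitude

    blocks, rows = [], []
    for d_idx, (day, n_day) in enumerate(zip(cfg.days, cfg.n_cells_per_day)):
        high = rng.random(n_day) < cfg.p_high
        lam1 = sched[d_idx] + rng.normal(0.0, jitter1, n_day)
        lam2 = np.where(high, -cfg.lambda2_magnitude, cfg.lambda2_magnitude)
        lam2 = lam2 + rng.normal(0.0, jitter2, n_day)
        log_block = (
            cfg.g0[None, :]
            + lam1[:, None] * cfg.g1[None, :]
            + lam2[:, None] * cfg.g2[None, :]
        )
        tip_flag = np.zeros(n_day, dtype=bool)
        for path_name, is_high in (("high", True), ("low", False)):
            spec = (cfg.tipping or {}).get(path_name)
            if spec is None or spec.day != day:
                continue
            members = np.flatnonzero(high == is_high)
            k = int(round(spec.fraction * members.size))
            if k == 0:
                continue
            chosen = rng.choice(members, size=k, replace=False)
            f = rng.normal(0.0, spec.latent_sd, k)
            log_block[chosen] += f[:, None] * spec.loading[None, :]
            tip_flag[chosen] = True
        log_block += rng.normal(0.0, cfg.noise_sd, log_block.shape)
        blocks.append(log_block)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"d{day}_c{i:03d}" for i in range(n_day)],
                    "day": day,
                    "path": np.where(high, "high", "low"),
                    "lambda1": lam1,
                    "lambda2": lam2,
                    "tipping": tip_flag,
                }
            )
        )

    log_values = np.vstack(blocks)
    truth_frame = pd.concat(rows, ignore_index=True)
    table = SingleCellTable(
        values=np.exp(log_values),
        cell_ids=tuple(truth_frame["cell_id"]),
        day=truth_frame["day"].to_numpy(),
        panel=panel,
        log_space=False,
        day_levels=cfg.days,
    )
    truth = GroundTruth(
        frame=truth_frame,
        loadings={
            "g0": cfg.g0,
            "g1": cfg.g1,
            "g2": cfg.g2,
            "h_high": (cfg.tipping or {}).get("high", TippingSpec()).loading,
            "h_low": (cfg.tipping or {}).get("low", TippingSpec()).loading,
        },
    )
    return table, truth


def truth_cluster_assignment(
    truth: GroundTruth,
) -> tuple[ClusterAssignment, dict[int, str], dict[str, int]]:
    """Oracle clustering from planted labels, for simulation studies.

    Each (path, day) group is one cluster; at a path's tipping day the
    flagged cells form their own cluster.  Returns the assignment, the
    cluster -> {"upper", "lower"} map (high = upper) and the planted tipping
    cluster id per path.
    """
    frame = truth.frame
    labels = np.full(len(frame), -1, dtype=int)
    day_of_cluster: dict[int, int] = {}
    path_of_cluster: dict[int, str] = {}
    tipping_cluster: dict[str, int] = {}
    next_id = 0
    days = sorted(frame["day"].unique())
    for path_name, path_label in (("high", "upper"), ("low", "lower")):
        for day in days:
            in_group = (frame["path"] == path_name) & (frame["day"] == day)
            tip = in_group & frame["tipping"]
            rest = in_group & ~frame["tipping"]
            for mask, is_tip in ((rest, False), (tip, True)):
                if not mask.any():
                    continue
                labels[mask.to_numpy()] = next_id
                day_of_cluster[next_id] = int(day)
                path_of_cluster[next_id] = path_label
                if is_tip:
                    tipping_cluster[path_label] = next_id
                next_id += 1
    k_per_day = {
        int(d): len({c for c, cd in day_of_cluster.items() if cd == d})
        for d in days
    }
    assignment = ClusterAssignment(
        labels=labels,
        day_of_cluster=day_of_cluster,
        k_per_day=k_per_day,
        markers_used=None,
        wss_curves={},
    )
    return assignment, path_of_cluster, tipping_cluster


def write_truth(truth: GroundTruth, path) -> None:
    truth.frame.to_csv(path, index=False)
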