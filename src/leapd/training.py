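"""Fitting the index model: grouping, per-electrode search, selection.

Training takes a labelled dataset and produces a fitted model:

1. subjects are split into cognitively normal / impaired groups (fixed
   score cutoff, e.g. MoCA < 26, or a median cut for continuous scores);
2. for every electrode, a grid search over (band, LPC order, subspace
   dimensions) finds the configuration whose single-electrode index best
   correlates (age-controlled Spearman) with the cognitive score on the
   training subjects;
3. the ``n_electrodes`` best electrodes by training correlation are kept;
4. a new subject is scored per selected electrode and the per-electrode
   indices fused by geometric mean.

Because the LPC encoding of a channel depends only on the recording (not
on any label), encodings are precomputed once in a :class:`FeatureCache`
and reused across grid points and cross-validation folds; labels and
scores only ever enter through the subspace fits and the selection
criterion, which are fold-local.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .io import Dataset, EEGRecording, SubjectRecord
from .lpc import autocorr_biased, levinson_durbin, lpc_encode
from .preprocess import Band, condition_channel, truncate_fraction
from .subspace import (
    AffineSubspace,
    _distances_to_subspace,
    combine_channels,
    distance_to_subspace,
    fit_affine_subspace,
    leapd_index,
)

__all__ = [
    "ChannelConfig",
    "ChannelModel",
    "LEAPDModel",
    "TrainingSettings",
    "FeatureCache",
    "assign_groups",
    "grid_search_channel",
    "select_electrodes",
    "fit_leapd",
    "score_subject",
    "classify_subject",
    "default_grid",
    "reduced_grid",
]

NORMAL, IMPAIRED = "normal", "impaired"


@dataclass(frozen=True)
class ChannelConfig:
    channel: str
    band: Band
    order: int
    k_normal: int = 3
    k_impaired: int = 3

    def sort_key(self):
        """Deterministic tie-break: lower order, then lower f_lo, ..."""
        return (self.order, self.band.f_lo, self.band.f_hi,
                self.k_normal, self.k_impaired)


@dataclass
class ChannelModel:
    config: ChannelConfig
    subspace_normal: AffineSubspace
    subspace_impaired: AffineSubspace
    train_correlation: float


@dataclass
class LEAPDModel:
    """Selected electrodes with their fitted configs and class subspaces."""

    channel_models: list[ChannelModel]
    threshold: float = 0.5
    grouping_rule: str = ""
    sample_rate: float = 500.0
    line_freq: float | None = 60.0

    def __post_init__(self) -> None:
        labels = [m.config.channel for m in self.channel_models]
        if len(set(labels)) != len(labels):
            raise ValueError("selected channel labels must be unique")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def channels(self) -> list[str]:
        return [m.config.channel for m in self.channel_models]

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "leapd-model", "version": 1,
            "threshold": self.threshold,
            "grouping_rule": self.grouping_rule,
            "sample_rate": self.sample_rate,
            "line_freq": self.line_freq,
            "channels": [
                {
                    "channel": m.config.channel,
                    "band": [m.config.band.f_lo, m.config.band.f_hi],
                    "order": m.config.order,
                    "k_normal": m.config.k_normal,
                    "k_impaired": m.config.k_impaired,
                    "train_correlation": m.train_correlation,
                    "normal": {
                        "centroid": m.subspace_normal.centroid.tolist(),
                        "basis": m.subspace_normal.basis.tolist(),
                    },
                    "impaired": {
                        "centroid": m.subspace_impaired.centroid.tolist(),
                        "basis": m.subspace_impaired.basis.tolist(),
                    },
                }
                for m in self.channel_models
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LEAPDModel":
        doc = json.loads(text)
        if doc.get("format") != "leapd-model":
            raise ValueError("not a leapd model document")
        models = []
        for ch in doc["channels"]:
            cfg = ChannelConfig(
                channel=ch["channel"], band=Band(*ch["band"]),
                order=ch["order"], k_normal=ch["k_normal"],
                k_impaired=ch["k_impaired"],
            )
            p = cfg.order
            models.append(
                ChannelModel(
                    config=cfg,
                    subspace_normal=AffineSubspace(
                        np.array(ch["normal"]["centroid"]),
                        np.array(ch["normal"]["basis"]).reshape(-1, p),
                        NORMAL,
                    ),
                    subspace_impaired=AffineSubspace(
                        np.array(ch["impaired"]["centroid"]),
                        np.array(ch["impaired"]["basis"]).reshape(-1, p),
                        IMPAIRED,
                    ),
                    train_correlation=ch["train_correlation"],
                )
            )
        return cls(
            channel_models=models, threshold=doc["threshold"],
            grouping_rule=doc["grouping_rule"], sample_rate=doc["sample_rate"],
            line_freq=doc["line_freq"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "LEAPDModel":
        return cls.from_json(Path(path).read_text())


def default_grid() -> list[tuple[Band, int, int, int]]:
    """Full search grid: (band, order, k_normal, k_impaired) combinations.

    Bands span low-frequency to broad ranges; f_hi must clear f_lo by
    more than 4 Hz.
    """
    bands = [
        Band(lo, hi)
        for lo, hi in product((1, 2, 4, 6, 8), (10, 13, 20, 30, 50))
        if hi > lo + 4
    ]
    return [
        (band, order, k, k)
        for band, order, k in product(bands, (6, 10, 14, 20), (1, 3, 5))
    ]


def reduced_grid() -> list[tuple[Band, int, int, int]]:
    """Small grid for quick runs: three bands x two orders, k = 3.

    The bands cover the theta/alpha shift region, a broad range, and the
    beta band, which is where the generator (and, in the study regime,
    cognition-linked EEG changes) put their signal.
    """
    bands = [Band(4, 14), Band(2, 30), Band(13, 30)]
    return [(band, order, 3, 3) for band, order in product(bands, (8, 12))]


@dataclass
class TrainingSettings:
    grid: list[tuple[Band, int, int, int]] = field(default_factory=reduced_grid)
    n_electrodes: int = 8
    threshold: float = 0.5
    line_freq: float | None = 60.0
    criterion: str = "rho"  # or "auc"


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def assign_groups(
    subjects: list[SubjectRecord],
    score_name: str,
    rule: str = "fixed_cutoff",
    cutoff: float = 26.0,
) -> dict[str, str]:
    """Assign each subject to the normal or impaired training group.

    ``fixed_cutoff``: score < cutoff -> impaired (the MoCA convention,
    cutoff 26).  ``median_cut``: score below the cohort median ->
    impaired-side group (used for continuous cognitive scores).
    """
    missing = [s.id for s in subjects if score_name not in s.scores]
    if missing:
        raise ValueError(f"subjects missing score {score_name!r}: {missing}")
    scores = np.array([s.scores[score_name] for s in subjects])
    if rule == "fixed_cutoff":
        cut = cutoff
    elif rule == "median_cut":
        cut = float(np.median(scores))
        if np.all(scores == scores[0]):
            raise ValueError("median cut impossible: all scores identical")
    else:
        raise ValueError(f"unknown grouping rule {rule!r}")
    groups = {
        s.id: (IMPAIRED if s.scores[score_name] < cut else NORMAL)
        for s in subjects
    }
    present = set(groups.values())
    if len(present) < 2:
        raise ValueError(
            f"grouping rule {rule!r} (cut {cut}) left the "
            f"{(set([NORMAL, IMPAIRED]) - present).pop()} group empty"
        )
    return groups


# ---------------------------------------------------------------------------
# feature cache
# ---------------------------------------------------------------------------

class FeatureCache:
    """Label-free LPC features for every (subject, channel, band, order).

    Stores, per (channel, band), each subject's autocorrelation sequence
    up to ``max_order`` computed from the conditioned channel; predictor
    coefficients for any order <= max_order are then derived on demand by
    Levinson-Durbin.  Safe to share across cross-validation folds and
    label shuffles: nothing here depends on scores or groups.
    """

    def __init__(
        self,
        ds: Dataset,
        max_order: int = 20,
        line_freq: float | None = 60.0,
        fraction: float = 1.0,
    ) -> None:
        self.ds = ds
        self.ids = ds.ids
        self.max_order = max_order
        self.line_freq = line_freq
        self.fraction = fraction
        self._autocorr: dict[tuple[str, Band], np.ndarray] = {}
        self._features: dict[tuple[str, Band, int], np.ndarray] = {}

    def _autocorrs(self, channel: str, band: Band) -> np.ndarray:
        key = (channel, band)
        if key not in self._autocorr:
            rows = []
            for sid in self.ids:
                rec = self.ds.recordings[sid]
                x = rec.channel(channel)
                if self.fraction < 1.0:
                    x = truncate_fraction(x, self.fraction)
                y = condition_channel(
                    x, rec.sample_rate, band, line_freq=self.line_freq
                )
                rows.append(autocorr_biased(y, self.max_order))
            self._autocorr[key] = np.array(rows)
        return self._autocorr[key]

    def features(self, channel: str, band: Band, order: int) -> np.ndarray:
        """(n_subjects, order) LPC coefficient matrix, row order = ds.ids."""
        if order > self.max_order:
            raise ValueError(
                f"order {order} exceeds cache max_order {self.max_order}"
            )
        key = (channel, band, order)
        if key not in self._features:
            R = self._autocorrs(channel, band)
            self._features[key] = np.array(
                [levinson_durbin(r, order)[0] for r in R]
            )
        return self._features[key]


def _channel_indices(
    F: np.ndarray, sub_normal: AffineSubspace, sub_impaired: AffineSubspace
) -> np.ndarray:
    """Single-channel index for a stack of LPC vectors."""
    d_n = _distances_to_subspace(F, sub_normal)
    d_i = _distances_to_subspace(F, sub_impaired)
    total = d_n + d_i
    out = np.full(F.shape[0], 0.5)
    nz = total > 0
    out[nz] = d_i[nz] / total[nz]
    return out


# ---------------------------------------------------------------------------
# grid search and fitting
# ---------------------------------------------------------------------------

def _score_config(
    idx: np.ndarray,
    scores: np.ndarray,
    ages: np.ndarray,
    labels_normal: np.ndarray,
    criterion: str,
) -> float:
    from .evaluation import roc_auc, spearman_partial

    try:
        if criterion == "rho":
            return spearman_partial(idx, scores, ages)[0]
        if criterion == "auc":
            return roc_auc(idx, labels_normal)[0]
    except ValueError:
        return -np.inf
    raise ValueError(f"unknown criterion {criterion!r}")


def grid_search_channel(
    ds: Dataset,
    groups: dict[str, str],
    score_name: str,
    channel: str,
    grid: list[tuple[Band, int, int, int]],
    cache: FeatureCache | None = None,
    subset: list[str] | None = None,
    criterion: str = "rho",
) -> ChannelModel:
    """Best (band, order, k) configuration for one electrode.

    Every grid point is fitted on the training subjects (class subspaces
    from the two groups) and scored by the age-controlled Spearman
    correlation between the resulting single-electrode index and the
    cognitive score (or by AUC).  Exact criterion ties break to the
    lower LPC order, then the lower band edge.
    """
    if not grid:
        raise ValueError("empty search grid")
    if cache is None:
        cache = FeatureCache(ds, max_order=max(g[1] for g in grid))
    ids = cache.ids
    row_of = {i: r for r, i in enumerate(ids)}
    rows = (
        np.arange(len(ids))
        if subset is None
        else np.array([row_of[i] for i in subset])
    )
    sel_ids = [ids[r] for r in rows]
    subj = {s.id: s for s in ds.subjects}
    scores = np.array([subj[i].scores[score_name] for i in sel_ids])
    ages = np.array([subj[i].age for i in sel_ids])
    labels_normal = np.array([groups[i] == NORMAL for i in sel_ids])
    i_norm = np.flatnonzero(labels_normal)
    i_imp = np.flatnonzero(~labels_normal)

    best: tuple | None = None
    for band, order, k_n, k_i in grid:
        # a class of m training vectors supports at most an (m-1)-dim flat
        k_n = min(k_n, len(i_norm) - 1)
        k_i = min(k_i, len(i_imp) - 1)
        if k_n < 0 or k_i < 0:
            continue
        F = cache.features(channel, band, order)[rows]
        s_n = fit_affine_subspace(F[i_norm], k_n, NORMAL)
        s_i = fit_affine_subspace(F[i_imp], k_i, IMPAIRED)
        idx = _channel_indices(F, s_n, s_i)
        crit = _score_config(idx, scores, ages, labels_normal, criterion)
        if not np.isfinite(crit):
            continue
        cfg = ChannelConfig(channel, band, order, k_n, k_i)
        cand = (-crit, cfg.sort_key(), cfg, s_n, s_i, crit)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise ValueError(
            f"no feasible configuration for channel {channel!r} "
            "(classes too small or criterion degenerate for every grid point)"
        )
    _, _, cfg, s_n, s_i, crit = best
    return ChannelModel(
        config=cfg, subspace_normal=s_n, subspace_impaired=s_i,
        train_correlation=float(crit),
    )


def select_electrodes(channel_models: list[ChannelModel], n: int) -> list[str]:
    """Labels of the n models with the highest training correlation.

    Ties break to lexicographic label order.
    """
    if n < 1:
        raise ValueError("need at least one electrode")
    if n > len(channel_models):
        raise ValueError(
            f"asked for {n} electrodes but only {len(channel_models)} models"
        )
    ranked = sorted(
        channel_models, key=lambda m: (-m.train_correlation, m.config.channel)
    )
    return [m.config.channel for m in ranked[:n]]


def fit_leapd(
    ds: Dataset,
    groups: dict[str, str],
    score_name: str = "moca",
    settings: TrainingSettings | None = None,
    cache: FeatureCache | None = None,
    subset: list[str] | None = None,
    channels: list[str] | None = None,
) -> LEAPDModel:
    """Fit the full model: grid search on every channel, keep the best n.

    ``subset`` restricts training to the named subjects (used by
    cross-validation folds); ``channels`` pins the electrode montage
    instead of selecting it (the fixed-montage mode).  Deterministic
    given its inputs.
    """
    settings = settings or TrainingSettings()
    train_ids = subset if subset is not None else ds.ids
    train_groups = {i: groups[i] for i in train_ids}
    present = set(train_groups.values())
    if len(present) < 2:
        raise ValueError("both cognitive groups must be present in training")
    all_channels = ds.channel_labels
    if settings.n_electrodes > len(all_channels):
        raise ValueError(
            f"n_electrodes={settings.n_electrodes} exceeds the "
            f"{len(all_channels)}-channel montage"
        )
    if cache is None:
        cache = FeatureCache(
            ds, max_order=max(g[1] for g in settings.grid),
            line_freq=settings.line_freq,
        )
    search_channels = channels if channels is not None else all_channels
    models = [
        grid_search_channel(
            ds, train_groups, score_name, ch, settings.grid,
            cache=cache, subset=train_ids, criterion=settings.criterion,
        )
        for ch in search_channels
    ]
    if channels is None:
        keep = set(select_electrodes(models, settings.n_electrodes))
        models = [m for m in models if m.config.channel in keep]
    rule = f"{score_name} grouping on training subjects"
    return LEAPDModel(
        channel_models=models, threshold=settings.threshold,
        grouping_rule=rule, sample_rate=ds.sample_rate,
        line_freq=settings.line_freq,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_subject(model: LEAPDModel, rec: EEGRecording) -> float:
    """Combined index in [0, 1] for one recording (high = normal)."""
    indices = []
    for m in model.channel_models:
        cfg = m.config
        v = lpc_encode(
            rec.channel(cfg.channel), rec.sample_rate, cfg.band, cfg.order,
            channel=cfg.channel, line_freq=model.line_freq,
        )
        d_n = distance_to_subspace(v.coefficients, m.subspace_normal)
        d_i = distance_to_subspace(v.coefficients, m.subspace_impaired)
        indices.append(leapd_index(d_n, d_i))
    return combine_channels(indices)


def score_rows(model: LEAPDModel, cache: FeatureCache, rows) -> np.ndarray:
    """Cache-backed scoring of the subjects at the given row positions."""
    rows = np.asarray(rows)
    per_channel = np.empty((len(model.channel_models), rows.size))
    for j, m in enumerate(model.channel_models):
        cfg = m.config
        F = cache.features(cfg.channel, cfg.band, cfg.order)[rows]
        per_channel[j] = _channel_indices(
            F, m.subspace_normal, m.subspace_impaired
        )
    return np.array([combine_channels(per_channel[:, t])
                     for t in range(rows.size)])


def classify_subject(model: LEAPDModel, rec: EEGRecording) -> str:
    """Threshold the combined index: index > threshold -> normal."""
    return NORMAL if score_subject(model, rec) > model.threshold else IMPAIRED
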