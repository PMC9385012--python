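"""Per-sample sputum analysis.

Each sample contributes two stained tubes (a leukocyte panel and an
epithelial panel) plus controls.  Both run through the same upstream
hierarchy — bead-calibrated scatter gate, FSC-H/FSC-A singlet gate,
viability gate (FVS510-positive events are dead; this is what removes
squamous epithelial cells) and a CD45 split — before tube-specific
subgating:

* leukocyte tube, within CD45+: gate 1 (CD66b/CD3/CD19-cocktail-positive
  granulocytes/lymphocytes), gate 2 (CD206-bright, FITC-autofluorescent
  alveolar macrophages) and gate 3 (CD206-intermediate interstitial
  macrophages);
* epithelial tube, within CD45-: EpCAM x panCK quadrants.

Positivity thresholds come from the unstained tube (viability, CD45) and
the FMO tubes (CD206, cocktail, EpCAM, panCK) as stringent upper quantiles
of the background.  The boundary between CD206-intermediate and CD206-bright
is the midpoint of a two-component Gaussian mixture fitted to CD206+ events
(falling back to a fixed offset above the FMO threshold when unimodal).

Finally, live single events are split into TCPP intensity strata: the
low/intermediate boundary is the crossing of the unstained and stained TCPP
kernel-density estimates, the intermediate/high boundary the density valley
below the upper TCPP mode (99.5th percentile when no upper mode exists).
Each stratum is profiled for scatter, CD45 split, leukocyte gates,
epithelial quadrants and EpCAM/panCK intensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .errors import InsufficientEventsError, MissingControlError
from .fcs_io import EventTable, default_transform
from .gating import (
    DEFAULT_CONTROL_QUANTILE,
    Gate,
    GateNode,
    GatingResult,
    channel_mfi,
    doublet_gate,
    evaluate_hierarchy,
    population_frequency,
    threshold_from_control,
)
from .synthetic import COCKTAIL, ControlSet, SampleTubes

__all__ = [
    "PipelineConfig",
    "TcppCuts",
    "SampleResult",
    "run_sample",
    "define_tcpp_strata",
    "stratum_profile",
    "STRATA",
]

STRATA = ("low", "im", "high")
_BIG = 50.0  # finite bound beyond any arcsinh-transformed intensity


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable analysis parameters (transformed-scale units unless noted)."""

    cofactor: float = 150.0
    control_quantile: float = DEFAULT_CONTROL_QUANTILE
    min_control_events: int = 1000
    doublet_k: float = 4.0
    min_pregate_events: int = 50
    # CD206 bright cutoff (alveolar vs interstitial)
    bright_min_events: int = 50
    bright_min_separation: float = 0.8
    bright_fallback_offset: float = 1.5
    # TCPP strata
    min_strata_events: int = 500
    kde_grid: int = 512
    kde_max_points: int = 20_000
    peak_prominence_frac: float = 0.02
    min_mode_separation: float = 0.8
    high_quantile_fallback: float = 0.995
    low_quantile_fallback: float = 0.9995
    # per-stratum metric stability floor
    min_stratum_events: int = 25


@dataclass(frozen=True)
class TcppCuts:
    low: float
    high: float
    flags: tuple[str, ...] = ()


@dataclass
class SampleResult:
    """Derived metrics plus the full gating results of one sample.

    ``metrics`` holds percentages, medians and MFIs (NaN when undefined);
    ``node_counts`` the per-gate event counts both tubes, from which every
    percentage can be re-derived (see :meth:`audit`).
    """

    sample_id: str
    metrics: dict[str, float] = field(default_factory=dict)
    node_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    cuts: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: dict[str, bool | list[str]] = field(default_factory=dict)
    gating: dict[str, GatingResult] = field(default_factory=dict, repr=False)

    @property
    def unanalyzable(self) -> bool:
        return bool(self.flags.get("unanalyzable", False))

    def to_json(self) -> str:
        """Deterministic, versioned JSON serialization (no event data)."""
        payload = {
            "schema": "sputumflow.sample_result/1",
            "sample_id": self.sample_id,
            "metrics": {k: self.metrics[k] for k in sorted(self.metrics)},
            "node_counts": {
                t: {k: v for k, v in sorted(c.items())}
                for t, c in sorted(self.node_counts.items())
            },
            "cuts": {t: dict(sorted(c.items())) for t, c in sorted(self.cuts.items())},
            "flags": {
                k: (sorted(v) if isinstance(v, list) else v)
                for k, v in sorted(self.flags.items())
            },
        }
        return json.dumps(payload, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "SampleResult":
        payload = json.loads(text)
        if payload.get("schema") != "sputumflow.sample_result/1":
            raise ValueError("unknown SampleResult schema")
        return cls(
            sample_id=payload["sample_id"],
            metrics=payload["metrics"],
            node_counts=payload["node_counts"],
            cuts=payload["cuts"],
            flags=payload["flags"],
        )

    def audit(self) -> bool:
        """Check every stored percentage against its own gate counts."""
        checks = []
        for tube, num, den, key in _PERCENT_AUDITS:
            counts = self.node_counts.get(tube, {})
            if num not in counts or den not in counts or key not in self.metrics:
                continue
            stored = self.metrics[key]
            if counts[den] == 0:
                checks.append(np.isnan(stored))
            else:
                checks.append(
                    np.isclose(stored, 100.0 * counts[num] / counts[den], atol=1e-9)
                )
        return all(checks)


_PERCENT_AUDITS = [
    ("leukocyte", "cd45pos", "live", "pct_cd45_of_live_singles"),
    ("leukocyte", "gate1", "cd45pos", "pct_gate1_of_cd45"),
    ("leukocyte", "gate2", "cd45pos", "pct_gate2_of_cd45"),
    ("leukocyte", "gate3", "cd45pos", "pct_gate3_of_cd45"),
    ("epithelial", "q_pp", "cd45neg", "pct_pp_of_cd45neg"),
    ("epithelial", "q_nn", "cd45neg", "pct_nn_of_cd45neg"),
    ("leukocyte", "tcpp_low", "live", "pct_tcpp_low_of_live_singles"),
    ("leukocyte", "tcpp_im", "live", "pct_tcpp_im_of_live_singles"),
    ("leukocyte", "tcpp_high", "live", "pct_tcpp_high_of_live_singles"),
]


# ---------------------------------------------------------------------------
# TCPP stratification
# ---------------------------------------------------------------------------

def _silverman_bw(x: np.ndarray) -> float:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(float(np.std(x)), iqr / 1.349) if iqr > 0 else float(np.std(x))
    return 0.9 * spread * len(x) ** (-0.2)


def _kde_on_grid(x: np.ndarray, grid: np.ndarray, max_points: int = 0) -> np.ndarray:
    """Gaussian KDE evaluated on a uniform grid via binned convolution.

    Binning at the grid resolution then convolving with the Gaussian kernel
    matches the exact KDE to well below the grid step, at linear cost.
    """
    step = grid[1] - grid[0]
    bw = max(_silverman_bw(x), step)
    edges = np.concatenate([grid - step / 2.0, [grid[-1] + step / 2.0]])
    counts, _ = np.histogram(np.clip(x, grid[0], grid[-1]), bins=edges)
    half = int(np.ceil(4.0 * bw / step))
    kernel = np.exp(-0.5 * ((np.arange(-half, half + 1) * step) / bw) ** 2)
    kernel /= kernel.sum()
    return np.convolve(counts, kernel, mode="same") / (len(x) * step)


def define_tcpp_strata(
    stained: np.ndarray,
    unstained: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> TcppCuts:
    """Derive the TCPP low/intermediate and intermediate/high cutpoints.

    Both inputs are transformed TCPP intensities of live single events
    (stained sample) and of the matched unstained control.  The low cut is
    where the unstained density overlay crosses under the stained density,
    searched between the two modes; the high cut is the density valley below
    the stained sample's upper mode, or its 99.5th percentile when the upper
    intensity structure is unimodal.
    """
    stained = np.asarray(stained, dtype=float)
    unstained = np.asarray(unstained, dtype=float)
    if len(stained) < config.min_strata_events or len(unstained) < config.min_strata_events:
        raise InsufficientEventsError(
            f"TCPP stratification needs >= {config.min_strata_events} events per input"
        )
    flags: list[str] = []
    lo = min(stained.min(), unstained.min())
    hi = max(stained.max(), unstained.max())
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, config.kde_grid)
    step = grid[1] - grid[0]
    f_s = _kde_on_grid(stained, grid, config.kde_max_points)
    f_u = _kde_on_grid(unstained, grid, config.kde_max_points)

    i_mode_u = int(np.argmax(f_u))

    # Stained density peaks: the uppermost well-separated peak marks the
    # TCPP-bright structure; the "main" mode is the highest peak below it
    # (the bulk of the sample), falling back to the global mode.
    peaks, _ = find_peaks(f_s, prominence=config.peak_prominence_frac * f_s.max())
    i_top = int(peaks[-1]) if len(peaks) else int(np.argmax(f_s))
    lower = [p for p in peaks if grid[i_top] - grid[p] >= config.min_mode_separation]
    i_main = int(max(lower, key=lambda p: f_s[p])) if lower else int(np.argmax(f_s))
    i_mode_s = i_main

    # ---- low cut: unstained/stained overlay crossing --------------------
    rel_diff = float(np.max(np.abs(f_u - f_s)) / max(f_u.max(), f_s.max()))
    if rel_diff <= 0.15 or abs(i_mode_s - i_mode_u) <= 2:
        # overlay and sample are indistinguishable (or share their mode):
        # the crossing degenerates to the common mode position
        low_cut = float(grid[min(i_mode_s, i_mode_u)])
        flags.append("degenerate_overlay")
    elif i_mode_s > i_mode_u:
        diff = f_u - f_s
        low_cut = None
        for i in range(i_mode_u + 1, i_mode_s + 1):
            if diff[i] <= 0 < diff[i - 1]:
                low_cut = float(grid[i - 1] + step * diff[i - 1] / (diff[i - 1] - diff[i]))
                break
        if low_cut is None:
            low_cut = float(np.quantile(unstained, config.low_quantile_fallback))
            flags.append("no_crossing")
    else:
        low_cut = float(np.quantile(unstained, config.low_quantile_fallback))
        flags.append("no_crossing")

    # ---- high cut: valley below the upper mode --------------------------
    if lower and i_top > i_main:
        valley = i_main + int(np.argmin(f_s[i_main : i_top + 1]))
        high_cut = float(grid[valley])
    else:
        high_cut = float(np.quantile(stained, config.high_quantile_fallback))
        flags.append("no_upper_mode")

    if high_cut <= low_cut:
        high_cut = float(np.quantile(stained, config.high_quantile_fallback))
        if high_cut <= low_cut:
            high_cut = float(np.nextafter(low_cut, np.inf))
        flags.append("cuts_reordered")
    return TcppCuts(low_cut, high_cut, tuple(flags))


# ---------------------------------------------------------------------------
# Threshold derivation from controls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeThresholds:
    fvs510: float
    cd45: float
    markers: dict[str, float]


def _pregate_nodes(table: EventTable, bead_gate: Gate, config: PipelineConfig) -> list[GateNode]:
    size_mask = bead_gate.membership(table)
    if int(size_mask.sum()) < config.min_pregate_events:
        raise InsufficientEventsError("too few events inside the size gate")
    singlet = doublet_gate(table.subset(size_mask), k=config.doublet_k)
    return [
        GateNode("size", bead_gate, "root"),
        GateNode("singlets", singlet, "size"),
    ]


def _control_live_singles(
    table: EventTable, bead_gate: Gate, fvs_thr: float | None, config: PipelineConfig
) -> tuple[EventTable, GatingResult]:
    nodes = _pregate_nodes(table, bead_gate, config)
    if fvs_thr is not None:
        nodes.append(
            GateNode("live", Gate("threshold_below", ("FVS510",), (fvs_thr,)), "singlets")
        )
    res = evaluate_hierarchy(table, nodes)
    leaf = "live" if fvs_thr is not None else "singlets"
    return table.subset(res.membership(leaf)), res


def _derive_tube_thresholds(
    unstained: EventTable,
    fmo_tubes: dict[str, EventTable],
    bead_gate: Gate,
    config: PipelineConfig,
) -> TubeThresholds:
    """Viability/CD45 cutoffs from the unstained tube, marker cutoffs from
    the FMO tubes (within the compartment each marker is read in)."""
    q, m = config.control_quantile, config.min_control_events
    pre, _ = _control_live_singles(unstained, bead_gate, None, config)
    fvs_thr = threshold_from_control(pre, "FVS510", q, m)
    live = pre.subset(Gate("threshold_below", ("FVS510",), (fvs_thr,)).membership(pre))
    cd45_thr = threshold_from_control(live, "CD45", q, m)

    markers: dict[str, float] = {}
    cd45_gate = Gate("threshold_above", ("CD45",), (cd45_thr,))
    for name, tube in fmo_tubes.items():
        live_t, _ = _control_live_singles(tube, bead_gate, fvs_thr, config)
        pos = cd45_gate.membership(live_t)
        if name == "CD206":
            markers[name] = threshold_from_control(live_t.subset(pos), "CD206", q, m)
        elif name == COCKTAIL:
            # background among CD45+ CD206- events: macrophage autofluorescence
            # sits above the lymphocyte/granulocyte FITC baseline by design
            cd206_thr = markers.get("CD206")
            if cd206_thr is None:
                raise MissingControlError("CD206 FMO must be derived before the cocktail")
            sub = pos & (live_t.channel("CD206") < cd206_thr)
            markers[name] = threshold_from_control(live_t.subset(sub), name, q, m)
        else:  # EpCAM / panCK are read in the CD45- compartment
            markers[name] = threshold_from_control(live_t.subset(~pos), name, q, m)
    return TubeThresholds(fvs_thr, cd45_thr, markers)


def _bright_cutoff(
    cd206: np.ndarray, fmo_thr: float, config: PipelineConfig
) -> tuple[float, bool]:
    """Boundary between CD206-intermediate and CD206-bright macrophages."""
    pos = cd206[cd206 >= fmo_thr]
    if len(pos) >= config.bright_min_events:
        gmm = GaussianMixture(n_components=2, random_state=0, n_init=1)
        gmm.fit(pos.reshape(-1, 1))
        means = np.sort(gmm.means_.ravel())
        weights = gmm.weights_.ravel()
        if (means[1] - means[0]) >= config.bright_min_separation and weights.min() >= 0.1:
            return float(means.mean()), False
    return fmo_thr + config.bright_fallback_offset, True


# ---------------------------------------------------------------------------
# Per-sample run
# ---------------------------------------------------------------------------

def _leukocyte_nodes(
    thr: TubeThresholds, bright: float, cuts: TcppCuts,
) -> list[GateNode]:
    fitc = thr.markers[COCKTAIL]
    cd206 = thr.markers["CD206"]
    return [
        GateNode("live", Gate("threshold_below", ("FVS510",), (thr.fvs510,)), "singlets"),
        GateNode("cd45pos", Gate("threshold_above", ("CD45",), (thr.cd45,)), "live"),
        GateNode("cd45neg", Gate("threshold_below", ("CD45",), (thr.cd45,)), "live"),
        GateNode(
            "gate1",
            Gate("rectangle", (COCKTAIL, "CD206"), (fitc, _BIG, -_BIG, cd206)),
            "cd45pos",
        ),
        GateNode(
            "gate2",
            Gate("rectangle", ("CD206", COCKTAIL), (bright, _BIG, fitc, _BIG)),
            "cd45pos",
        ),
        GateNode(
            "gate3",
            Gate("rectangle", ("CD206", COCKTAIL), (cd206, bright, -_BIG, fitc)),
            "cd45pos",
        ),
    ] + _strata_nodes(cuts)


def _epithelial_nodes(thr: TubeThresholds, cuts: TcppCuts) -> list[GateNode]:
    e = thr.markers["EpCAM"]
    p = thr.markers["panCK"]
    quad = lambda name, xlo, xhi, ylo, yhi: GateNode(  # noqa: E731
        name, Gate("rectangle", ("EpCAM", "panCK"), (xlo, xhi, ylo, yhi)), "cd45neg"
    )
    return [
        GateNode("live", Gate("threshold_below", ("FVS510",), (thr.fvs510,)), "singlets"),
        GateNode("cd45pos", Gate("threshold_above", ("CD45",), (thr.cd45,)), "live"),
        GateNode("cd45neg", Gate("threshold_below", ("CD45",), (thr.cd45,)), "live"),
        quad("q_pp", e, _BIG, p, _BIG),
        quad("q_pn", e, _BIG, -_BIG, p),
        quad("q_np", -_BIG, e, p, _BIG),
        quad("q_nn", -_BIG, e, -_BIG, p),
    ] + _strata_nodes(cuts)


def _strata_nodes(cuts: TcppCuts) -> list[GateNode]:
    return [
        GateNode("tcpp_low", Gate("interval", ("TCPP",), (-_BIG, cuts.low)), "live"),
        GateNode("tcpp_im", Gate("interval", ("TCPP",), (cuts.low, cuts.high)), "live"),
        GateNode("tcpp_high", Gate("interval", ("TCPP",), (cuts.high, _BIG)), "live"),
    ]


def _freq(res: GatingResult, node: str, den: str) -> float:
    return population_frequency(res, node, den)


def _tube_side_metrics(
    prefix: str,
    tube: str,
    table: EventTable,
    res: GatingResult,
    mask: np.ndarray,
    config: PipelineConfig,
) -> dict[str, float]:
    """Metrics of one tube restricted to an event subset (a TCPP stratum, or
    all live singles when ``mask`` covers them)."""
    out: dict[str, float] = {}
    n = int(mask.sum())
    nan = float("nan")
    if tube == "leukocyte":
        if n < config.min_stratum_events:
            return {
                f"{prefix}ssc_median": nan, f"{prefix}pct_cd45": nan,
                f"{prefix}pct_gate1_of_cd45": nan, f"{prefix}pct_gate2_of_cd45": nan,
                f"{prefix}pct_gate3_of_cd45": nan,
            }
        ssc = table.channel("SSC-A")[mask]
        out[f"{prefix}ssc_median"] = float(np.median(ssc))
        cd45 = mask & res.membership("cd45pos")
        out[f"{prefix}pct_cd45"] = 100.0 * int(cd45.sum()) / n
        n_cd45 = int(cd45.sum())
        for g in ("gate1", "gate2", "gate3"):
            if n_cd45 < config.min_stratum_events:
                out[f"{prefix}pct_{g}_of_cd45"] = nan
            else:
                out[f"{prefix}pct_{g}_of_cd45"] = (
                    100.0 * int((mask & res.membership(g)).sum()) / n_cd45
                )
        return out
    # epithelial tube
    neg = mask & res.membership("cd45neg")
    n_neg = int(neg.sum())
    if n_neg < config.min_stratum_events:
        return {
            f"{prefix}pct_pp_of_cd45neg": nan,
            f"{prefix}epcam_mfi_pp": nan, f"{prefix}panck_mfi_pp": nan,
        }
    pp = neg & res.membership("q_pp")
    out[f"{prefix}pct_pp_of_cd45neg"] = 100.0 * int(pp.sum()) / n_neg
    if int(pp.sum()) >= config.min_stratum_events:
        out[f"{prefix}epcam_mfi_pp"] = channel_mfi(table, pp, "EpCAM")
        out[f"{prefix}panck_mfi_pp"] = channel_mfi(table, pp, "panCK")
    else:
        out[f"{prefix}epcam_mfi_pp"] = nan
        out[f"{prefix}panck_mfi_pp"] = nan
    return out


def run_sample(
    tubes: SampleTubes,
    controls: ControlSet,
    bead_gate: Gate,
    config: PipelineConfig = PipelineConfig(),
    tcpp_cuts: dict[str, TcppCuts] | None = None,
) -> SampleResult:
    """Run the full per-sample analysis and fill a :class:`SampleResult`.

    ``tcpp_cuts`` overrides the per-tube TCPP cutpoints (keys ``leukocyte``
    / ``epithelial``); by default they are derived per sample from the
    stained tube and its unstained control.
    """
    if controls is None:
        raise MissingControlError("controls are required to derive thresholds")
    sample_id = tubes.meta.get("sample_id", tubes.leukocyte.sample_id)
    result = SampleResult(sample_id=sample_id)
    result.flags["unanalyzable"] = False
    result.flags["notes"] = []

    tube_tables = {
        "leukocyte": default_transform(tubes.leukocyte, config.cofactor),
        "epithelial": default_transform(tubes.epithelial, config.cofactor),
    }
    unstained = {
        "leukocyte": default_transform(controls.unstained_leukocyte, config.cofactor),
        "epithelial": default_transform(controls.unstained_epithelial, config.cofactor),
    }
    fmo = {
        "leukocyte": {
            "CD206": default_transform(controls.fmo_cd206, config.cofactor),
            COCKTAIL: default_transform(controls.fmo_cocktail, config.cofactor),
        },
        "epithelial": {
            "EpCAM": default_transform(controls.fmo_epcam, config.cofactor),
            "panCK": default_transform(controls.fmo_panck, config.cofactor),
        },
    }

    results: dict[str, GatingResult] = {}
    try:
        for tube, table in tube_tables.items():
            thr = _derive_tube_thresholds(unstained[tube], fmo[tube], bead_gate, config)
            pre = _pregate_nodes(table, bead_gate, config)
            pre_res = evaluate_hierarchy(table, pre)
            live_mask = (
                pre_res.membership("singlets")
                & Gate("threshold_below", ("FVS510",), (thr.fvs510,)).membership(table)
            )
            if int(live_mask.sum()) == 0:
                raise InsufficientEventsError("no live single events")

            if tcpp_cuts is not None and tube in tcpp_cuts:
                cuts = tcpp_cuts[tube]
            else:
                un_pre, _ = _control_live_singles(unstained[tube], bead_gate, None, config)
                cuts = define_tcpp_strata(
                    table.channel("TCPP")[live_mask],
                    un_pre.channel("TCPP"),
                    config,
                )
            result.cuts[tube] = {"tcpp_low": cuts.low, "tcpp_high": cuts.high}
            result.flags["notes"] += [f"{tube}:{f}" for f in cuts.flags]

            if tube == "leukocyte":
                cd206 = table.channel("CD206")[
                    live_mask
                    & Gate("threshold_above", ("CD45",), (thr.cd45,)).membership(table)
                ]
                bright, fell_back = _bright_cutoff(cd206, thr.markers["CD206"], config)
                if fell_back:
                    result.flags["notes"].append("leukocyte:bright_fallback")
                nodes = pre + _leukocyte_nodes(thr, bright, cuts)
                result.cuts[tube]["cd206_bright"] = bright
            else:
                nodes = pre + _epithelial_nodes(thr, cuts)
            result.cuts[tube].update(
                {"fvs510": thr.fvs510, "cd45": thr.cd45, **thr.markers}
            )
            results[tube] = evaluate_hierarchy(table, nodes)
    except InsufficientEventsError as exc:
        result.flags["unanalyzable"] = True
        result.flags["notes"].append(f"unanalyzable:{exc}")
        return result

    result.gating = results
    for tube, res in results.items():
        result.node_counts[tube] = dict(res.counts)

    lres, eres = results["leukocyte"], results["epithelial"]
    ltab, etab = tube_tables["leukocyte"], tube_tables["epithelial"]
    m = result.metrics
    m["pct_cd45_of_live_singles"] = _freq(lres, "cd45pos", "live")
    for g in ("gate1", "gate2", "gate3"):
        m[f"pct_{g}_of_cd45"] = _freq(lres, g, "cd45pos")
    n_live = lres.count("live")
    n_mac = lres.count("gate2") + lres.count("gate3")
    m["pct_macrophage_of_live_singles"] = (
        100.0 * n_mac / n_live if n_live else float("nan")
    )
    for q in ("q_pp", "q_pn", "q_np", "q_nn"):
        m[f"pct_{q[2:]}_of_cd45neg"] = _freq(eres, q, "cd45neg")
    for s in STRATA:
        m[f"pct_tcpp_{s}_of_live_singles"] = _freq(lres, f"tcpp_{s}", "live")

    # whole-sample profile (the trivial stratum covering all live singles)
    m.update(
        _tube_side_metrics("", "leukocyte", ltab, lres, lres.membership("live"), config)
    )
    m.update(
        _tube_side_metrics("", "epithelial", etab, eres, eres.membership("live"), config)
    )
    # per-stratum profiles
    for s in STRATA:
        m[f"tcpp_{s}_pct_of_live_singles"] = _freq(lres, f"tcpp_{s}", "live")
        m.update(
            _tube_side_metrics(
                f"tcpp_{s}_", "leukocyte", ltab, lres,
                lres.membership(f"tcpp_{s}"), config,
            )
        )
        m.update(
            _tube_side_metrics(
                f"tcpp_{s}_", "epithelial", etab, eres,
                eres.membership(f"tcpp_{s}"), config,
            )
        )
    return result


_STRATUM_KEYS = (
    "pct_of_live_singles", "ssc_median", "pct_cd45",
    "pct_gate1_of_cd45", "pct_gate2_of_cd45", "pct_gate3_of_cd45",
    "pct_pp_of_cd45neg", "epcam_mfi_pp", "panck_mfi_pp",
)


def stratum_profile(result: SampleResult, stratum: str) -> dict[str, float]:
    """The metric bundle of one TCPP stratum (NaN entries were below the
    event floor and are undefined)."""
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    prefix = f"tcpp_{stratum}_"
    return {
        key: result.metrics.get(prefix + key, float("nan")) for key in _STRATUM_KEYS
    }
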