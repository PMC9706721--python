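"""Synthetic fermentation-study generator with planted ground truth.

Emulates the study design: 3 treatment types (DD two-strain consortium,
CD single strain, PD uninoculated control) x 10 sampling days
(3,4,5,6,7,10,12,15,17,28) x 3 replicates = 90 samples, a three-phase
temperature profile peaking at 58-61 degC, and moisture/acidity that
decline in expectation through the rising and stable-high phases.

Communities are compositional: per-taxon log relative weights are a
heavy-tailed log-normal baseline plus planted effects, softmax-normalized
and sampled multinomially (or per-taxon negative-binomially) at a
negative-binomial sequencing depth around 80,000 reads. Planted roles:

* param_driven  - log-weight linear in one standardized fermentation
  parameter (slope / residual-noise ratio tuned for |rho| ~ 0.8);
* type_responsive - a log2 fold change in one enriched treatment type,
  plus a shared within-group latent so co-responding taxa co-occur; their
  baseline is shifted downward (rare-taxon regime);
* enzyme_linked - loaded on a per-activity latent factor; each enzymatic
  activity is a deterministic function (linear / quadratic / sinusoidal /
  step) of its linked taxa's summed relative abundance plus Gaussian
  noise, so nonlinear links are invisible to rank correlation but visible
  to MIC;
* background    - optionally organized into correlated "guilds" so the
  co-occurrence network has non-trivial modules.

A small number of type_responsive taxa are additionally coupled to an
activity latent ("overlap" taxa, at most one activity each): they are the
planted mechanism by which inoculation-responsive taxa carry enzymatic
function, and give each activity a distinct expected effect intensity.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ACTIVITIES,
    PARAMETERS,
    CountTable,
    Kingdom,
    MtdType,
    SampleInfo,
    Taxonomy,
)

SAMPLING_DAYS = (3, 4, 5, 6, 7, 10, 12, 15, 17, 28)
TYPES = ("DD", "CD", "PD")
REPLICATES = (1, 2, 3)

ACTIVITY_FORMS = {"LA": "linear", "SA": "quadratic", "EA": "sinusoidal", "FA": "step"}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the package's standard scenario."""

    n_background: int = 420
    n_param_driven: int = 30
    n_type_responsive: int = 30
    n_enzyme_linked: int = 20  # split evenly over the four activities
    depth_mean: float = 80_000.0
    depth_dispersion: float = 0.02
    base_log_sd: float = 1.5
    responsive_base_shift: float = -2.0  # responsive taxa live in the rare regime
    responsive_log2fc: float = 2.0
    responsive_latent_loading: float = 0.8
    param_slope: float = 2.0 / 3.0  # slope/noise ratio gives |rho| ~ 0.8
    enzyme_latent_loading: float = 1.5
    overlap_latent_loading: float = 1.0
    noise_sd: float = 0.5
    activity_noise_frac: float = 0.10
    activity_scale: float = 100.0
    overlap_counts: Mapping[str, int] = field(
        default_factory=lambda: {"LA": 2, "SA": 3, "EA": 1, "FA": 1}
    )
    n_guilds: int = 6
    guild_fraction: float = 0.65
    guild_loading: float = 1.5
    guild_day_weight: float = 0.8  # share of guild-latent SD that follows succession
    count_model: str = "multinomial"  # or "nb"
    nb_count_dispersion: float = 0.05
    kingdom: Kingdom = Kingdom.bacteria
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_asvs <= 0:
            raise ValueError("config with zero total ASVs")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be > 0")
        if self.count_model not in ("multinomial", "nb"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if sum(self.overlap_counts.values()) > self.n_type_responsive:
            raise ValueError("more overlap taxa than type_responsive taxa")

    @property
    def total_asvs(self) -> int:
        return (
            self.n_background
            + self.n_param_driven
            + self.n_type_responsive
            + self.n_enzyme_linked
        )

    def null(self) -> "SimConfig":
        """Zero-effect variant: no planted structure beyond the baseline."""
        return dc_replace(
            self,
            responsive_log2fc=0.0,
            responsive_latent_loading=0.0,
            param_slope=0.0,
            enzyme_latent_loading=0.0,
            guild_loading=0.0,
        )

    def small(self) -> "SimConfig":
        """Scaled-down variant for fast tests (depth 5,000, fewer taxa)."""
        return dc_replace(
            self,
            n_background=80,
            n_param_driven=10,
            n_type_responsive=12,
            n_enzyme_linked=8,
            depth_mean=5_000.0,
            overlap_counts={"LA": 1, "SA": 2, "EA": 0, "FA": 0},
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-ASV roles and effect parameters for recovery tests."""

    roles: Mapping[str, str]  # asv_id -> role
    param_drivers: Mapping[str, tuple[str, int]]  # pASV truth: (parameter, sign)
    responsive: Mapping[str, tuple[str, float]]  # (enriched type, log2fc)
    enzyme_links: Mapping[str, tuple[str, str]]  # (activity, form), incl. overlap taxa
    activity_truth: Mapping[str, frozenset[str]]  # activity -> linked ASVs

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, s in self.activity_truth.items():
            if seen & set(s):
                raise ValueError("an ASV appears in two activities' truth sets")
            seen |= set(s)

    def role_set(self, role: str) -> set[str]:
        return {a for a, r in self.roles.items() if r == role}

    def frame(self) -> pd.DataFrame:
        rows = []
        for asv, role in self.roles.items():
            param, sign = self.param_drivers.get(asv, ("", 0))
            etype, fc = self.responsive.get(asv, ("", 0.0))
            act, form = self.enzyme_links.get(asv, ("", ""))
            rows.append(
                {
                    "asv_id": asv,
                    "role": role,
                    "driving_parameter": param,
                    "parameter_sign": sign,
                    "enriched_type": etype,
                    "log2fc": fc,
                    "linked_activity": act,
                    "link_form": form,
                }
            )
        return pd.DataFrame(rows).set_index("asv_id")


# ---------------------------------------------------------------------------
# design


def _temperature_profile(day: float, fortified: bool) -> float:
    """Three-phase expected temperature (degC): rise to 30-45 within days
    2-3, peak 58-61 in the stable phase, below 35 in the cooling phase.
    Fortified bricks warm slightly faster early on."""
    base = np.interp(day, [0, 3, 7, 12, 15, 20, 28], [25, 40, 59.5, 58.5, 34, 30, 27])
    if fortified and day <= 6:
        base += 1.5
    return float(base)


def generate_design(seed: int = 0) -> list[SampleInfo]:
    """The 3 types x 10 days x 3 replicates design (90 samples).

    Parameter values are the deterministic phase profiles plus replicate
    noise; moisture and acidity decline in expectation. Activities are
    left empty (filled by ``generate_activities``).
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in TYPES:
        for day in SAMPLING_DAYS:
            for rep in REPLICATES:
                temp = _temperature_profile(day, t in ("DD", "CD")) + rng.normal(0, 1.0)
                moist = float(
                    np.interp(day, [0, 6, 12, 28], [0.40, 0.30, 0.20, 0.15])
                    + rng.normal(0, 0.01)
                )
                acid = float(
                    np.interp(day, [0, 6, 12, 28], [1.20, 0.90, 0.60, 0.50])
                    + rng.normal(0, 0.03)
                )
                out.append(
                    SampleInfo(
                        sample_id=f"{t}_d{day:02d}_r{rep}",
                        mtd_type=MtdType(t),
                        day=day,
                        replicate=rep,
                        temperature=round(temp, 3),
                        moisture=round(min(max(moist, 0.0), 1.0), 4),
                        acidity=round(max(acid, 0.0), 4),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# community


def _assign_roles(config: SimConfig, prefix: str) -> SyntheticTruth:
    n_per_act = config.n_enzyme_linked // len(ACTIVITIES)
    roles: dict[str, str] = {}
    param_drivers: dict[str, tuple[str, int]] = {}
    responsive: dict[str, tuple[str, float]] = {}
    enzyme_links: dict[str, tuple[str, str]] = {}
    activity_truth: dict[str, set[str]] = {a: set() for a in ACTIVITIES}
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"{prefix}{idx:04d}"

    for i in range(config.n_param_driven):
        asv = next_id()
        roles[asv] = "param_driven"
        param_drivers[asv] = (PARAMETERS[i % 3], 1 if i % 2 == 0 else -1)
    responsive_ids = []
    for i in range(config.n_type_responsive):
        asv = next_id()
        roles[asv] = "type_responsive"
        responsive[asv] = (TYPES[i % 3], config.responsive_log2fc)
        responsive_ids.append(asv)
    extra = config.n_enzyme_linked - n_per_act * len(ACTIVITIES)
    for ai, act in enumerate(ACTIVITIES):
        n_here = n_per_act + (1 if ai < extra else 0)
        for _ in range(n_here):
            asv = next_id()
            roles[asv] = "enzyme_linked"
            enzyme_links[asv] = (act, ACTIVITY_FORMS[act])
            activity_truth[act].add(asv)
    for _ in range(config.n_background):
        roles[next_id()] = "background"
    # overlap: deterministically couple the first free responsive taxa
    cursor = 0
    for act in ACTIVITIES:
        for _ in range(int(config.overlap_counts.get(act, 0))):
            asv = responsive_ids[cursor]
            cursor += 1
            enzyme_links[asv] = (act, ACTIVITY_FORMS[act])
            activity_truth[act].add(asv)
    return SyntheticTruth(
        roles=roles,
        param_drivers=param_drivers,
        responsive=responsive,
        enzyme_links=enzyme_links,
        activity_truth={a: frozenset(s) for a, s in activity_truth.items()},
    )


def generate_community(
    design: Sequence[SampleInfo], config: SimConfig
) -> tuple[CountTable, SyntheticTruth]:
    """Compositional counts with planted effects; returns (table, truth)."""
    rng = np.random.default_rng(config.seed)
    prefix = "bASV_" if config.kingdom == Kingdom.bacteria else "fASV_"
    truth = _assign_roles(config, prefix)
    asv_ids = list(truth.roles)
    n_asv, n_samp = len(asv_ids), len(design)
    params = {
        p: np.array([getattr(s, p) for s in design], dtype=float) for p in PARAMETERS
    }
    z = {}
    for p, v in params.items():
        sd = v.std()
        z[p] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    types = np.array([s.mtd_type.value for s in design])

    base = rng.normal(0.0, config.base_log_sd, size=n_asv)
    logw = np.tile(base[:, None], (1, n_samp))

    # activity and response latents are iid over samples (see docs on why
    # they are deliberately not day-structured); background guilds follow
    # succession: a smooth day "bloom" plus sample-level noise
    act_latent = {a: rng.standard_normal(n_samp) for a in ACTIVITIES}
    type_latent = {t: rng.standard_normal(n_samp) for t in TYPES}
    days = np.array([s.day for s in design], dtype=float)
    n_guilds = max(config.n_guilds, 1)
    centers = np.linspace(days.min(), days.max(), n_guilds)
    w_day = np.clip(config.guild_day_weight, 0.0, 1.0)
    w_iid = np.sqrt(1.0 - w_day ** 2)
    guild_latent = np.empty((n_guilds, n_samp))
    for gi in range(n_guilds):
        bump = np.exp(-((days - centers[gi]) ** 2) / (2.0 * 5.0 ** 2))
        sd = bump.std()
        z_bump = (bump - bump.mean()) / sd if sd > 0 else np.zeros_like(bump)
        guild_latent[gi] = w_day * z_bump + w_iid * rng.standard_normal(n_samp)

    background_ids = [a for a in asv_ids if truth.roles[a] == "background"]
    n_guilded = int(config.guild_fraction * len(background_ids))
    # succession guilds live among the sub-dominant taxa: the heavy upper
    # tail of the baseline stays temporally stable so the compositional
    # denominator does not impose a spurious common trend
    idx_of = {a: i for i, a in enumerate(asv_ids)}
    by_base = sorted(background_ids, key=lambda a: base[idx_of[a]])
    guild_of = {a: gi % n_guilds for gi, a in enumerate(by_base[:n_guilded])}

    ln2 = np.log(2.0)
    for i, asv in enumerate(asv_ids):
        role = truth.roles[asv]
        if role == "param_driven":
            p, sign = truth.param_drivers[asv]
            logw[i] += config.param_slope * sign * z[p]
        elif role == "type_responsive":
            etype, fc = truth.responsive[asv]
            logw[i] += config.responsive_base_shift
            logw[i] += np.where(types == etype, fc * ln2, 0.0)
            if asv in truth.enzyme_links:
                # overlap taxon: its co-variation runs through the activity
                # latent instead of the response-group latent
                act, _ = truth.enzyme_links[asv]
                logw[i] += config.overlap_latent_loading * act_latent[act]
            else:
                logw[i] += config.responsive_latent_loading * type_latent[etype]
        elif role == "enzyme_linked":
            act, _ = truth.enzyme_links[asv]
            logw[i] += config.enzyme_latent_loading * act_latent[act]
        elif asv in guild_of:
            logw[i] += config.guild_loading * guild_latent[guild_of[asv]]
    logw += rng.normal(0.0, config.noise_sd, size=(n_asv, n_samp))

    probs = np.exp(logw - logw.max(axis=0))
    probs /= probs.sum(axis=0)

    r_depth = 1.0 / max(config.depth_dispersion, 1e-9)
    depth = rng.negative_binomial(
        r_depth, r_depth / (r_depth + config.depth_mean), size=n_samp
    )
    depth = np.maximum(depth, 1_000)

    counts = np.empty((n_asv, n_samp), dtype=np.int64)
    if config.count_model == "multinomial":
        for s in range(n_samp):
            counts[:, s] = rng.multinomial(depth[s], probs[:, s])
    else:
        mu = probs * depth[None, :]
        r = 1.0 / config.nb_count_dispersion
        counts[:] = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9)))
    # compositional tables must not contain empty samples
    empty = counts.sum(axis=0) == 0
    counts[0, empty] = 1
    table = CountTable(
        pd.DataFrame(counts, index=asv_ids, columns=[s.sample_id for s in design]),
        config.kingdom,
    )
    return table, truth


# ---------------------------------------------------------------------------
# activities


def _form_value(agg: np.ndarray, form: str) -> np.ndarray:
    """Deterministic link function applied to the aggregate relative
    abundance of an activity's linked taxa."""
    if form == "linear":
        return agg.copy()
    rng01 = np.ptp(agg)
    g = (agg - agg.min()) / rng01 if rng01 > 0 else np.zeros_like(agg)
    if form == "quadratic":
        return (g - 0.5) ** 2
    if form == "sinusoidal":
        return np.sin(2.0 * np.pi * 1.25 * g)
    if form == "step":
        return (g >= np.median(g)).astype(float)
    raise ValueError(f"unknown link form {form!r}")


def generate_activities(
    design: Sequence[SampleInfo],
    table: CountTable,
    truth: SyntheticTruth,
    config: SimConfig,
) -> list[SampleInfo]:
    """Fill the four enzymatic activities from the linked taxa.

    activity = scale * form(sum of linked relative abundances) + Gaussian
    noise with SD = activity_noise_frac * SD(signal), shifted to stay
    non-negative. Raises if any activity has an empty truth set.
    """
    rng = np.random.default_rng(config.seed + 104729)  # independent substream
    rel = table.counts().astype(float)
    rel /= rel.sum(axis=0)
    asv_index = {a: i for i, a in enumerate(table.asv_ids)}
    col_of = {sid: j for j, sid in enumerate(table.sample_ids)}
    cols = [col_of[s.sample_id] for s in design]
    values: dict[str, np.ndarray] = {}
    for act in ACTIVITIES:
        linked = sorted(truth.activity_truth[act])
        if not linked:
            raise ValueError(f"activity {act} has an empty truth set")
        agg = rel[[asv_index[a] for a in linked], :][:, cols].sum(axis=0)
        signal = _form_value(agg, ACTIVITY_FORMS[act]) * config.activity_scale
        sd = signal.std()
        noise = rng.normal(0.0, config.activity_noise_frac * sd, size=len(design))
        v = signal + noise
        if ACTIVITY_FORMS[act] != "linear":
            v = v - v.min()  # keep activities non-negative
        values[act] = np.maximum(v, 0.0)
    out = []
    for j, s in enumerate(design):
        acts = {a: float(values[a][j]) for a in ACTIVITIES}
        out.append(dc_replace(s, activities=acts))
    return out


def synthetic_taxonomy(table: CountTable, seed: int = 0) -> Taxonomy:
    """Plausible genus labels for a synthetic table (round-trip plumbing)."""
    genera_b = ("Weissella", "Bacillus", "Lactobacillus", "Staphylococcus",
                "Enterobacter", "Pediococcus", "Leuconostoc", "Acinetobacter")
    genera_f = ("Pichia", "Hyphopichia", "Rhizomucor", "Thermomyces",
                "Rhizopus", "Wickerhamomyces", "Thermoascus", "Saccharomycopsis")
    rng = np.random.default_rng(seed)
    bacterial = table.kingdom == Kingdom.bacteria
    pool = genera_b if bacterial else genera_f
    king = "Bacteria" if bacterial else "Fungi"
    lineages = {}
    for asv in table.asv_ids:
        genus = pool[int(rng.integers(len(pool)))]
        lineages[asv] = (king, "", "", "", "", genus)
    return Taxonomy(lineages)


def generate_dataset(
    seed: int = 0,
    config: SimConfig | None = None,
    fungal_config: SimConfig | None = None,
) -> dict:
    """One full synthetic study: design, bacterial + fungal tables, truth,
    metadata with activities driven by the bacterial community."""
    cfg_b = dc_replace(config or SimConfig(), kingdom=Kingdom.bacteria, seed=seed)
    cfg_f = fungal_config or dc_replace(
        SimConfig(
            n_background=160,
            n_param_driven=12,
            n_type_responsive=15,
            n_enzyme_linked=0,
            overlap_counts={},
            n_guilds=4,
        ),
        kingdom=Kingdom.fungi,
        seed=seed + 1,
    )
    design = generate_design(seed)
    table_b, truth_b = generate_community(design, cfg_b)
    table_f, truth_f = generate_community(design, cfg_f)
    meta = generate_activities(design, table_b, truth_b, cfg_b)
    return {
        "design": design,
        "meta": meta,
        "tables": {"bacteria": table_b, "fungi": table_f},
        "truths": {"bacteria": truth_b, "fungi": truth_f},
        "configs": {"bacteria": cfg_b, "fungi": cfg_f},
    }
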