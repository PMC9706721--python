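"""Model/Results facade over the full response-analysis cascade.

``BioturbationAnalysis`` is built from per-kingdom count tables plus
sample metadata (or directly from the synthetic generator) and a
``PipelineConfig``; ``fit()`` runs normalization, the parameter screen,
indicator analysis, NB-LRT differential abundance, MIC association,
network construction and the pASV -> iASV -> brASV -> bsASV -> eASV
classification, returning a ``BioturbationResults`` with every
intermediate statistic, the derived effect sizes, and a ``summary()``
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    build_classification,
    classification_frame,
    derive_brasv,
    derive_bsasv,
    easv_module_coverage,
    effect_intensity,
    effect_size,
    identify_bsmodules,
    identify_easv,
    identify_pasv,
    union,
)
from .config import PipelineConfig
from .data_model import (
    ACTIVITIES,
    CountTable,
    SampleInfo,
    align,
    metadata_to_frame,
    read_count_table,
    read_metadata,
)
from .diffabund import estimate_common_dispersion, nb_lrt, select_differential
from .indicator import indval, select_iasv
from .mic import mic_matrix
from .network import (
    CooccurrenceNetwork,
    build_network,
    degree_abundance_profile,
    detect_modules,
    filter_for_network,
    module_abundance,
    profile_summary,
)
from .normalization import cpm, tmm_factors

log = logging.getLogger(__name__)


@dataclass
class KingdomResults:
    """Per-kingdom stage outputs of the cascade."""

    kingdom: str
    factors: object
    cpm: pd.DataFrame  # asv x sample
    pasv: set[str]
    pasv_drivers: dict
    indicator_results: list
    iasv: dict[str, set[str]]
    brasv: dict[str, set[str]]
    bsasv: dict[str, set[str]]
    dispersion: float
    diffabund_results: list
    differential: set[str]
    effect_size_pct: float
    classification: list
    filtered_asvs: list[str]


@dataclass
class BioturbationResults:
    """Fitted cascade: estimates, networks and derived summaries."""

    config: PipelineConfig
    meta: list[SampleInfo]
    kingdoms: dict[str, KingdomResults]
    mic: pd.DataFrame | None  # ASV x activity
    easv: dict[str, set[str]]
    strong_easv: dict[str, set[str]]
    pooled_network: CooccurrenceNetwork | None
    type_networks: dict[str, CooccurrenceNetwork] = field(default_factory=dict)
    bsmodules: set[int] = field(default_factory=set)
    effect_intensity: dict[str, float] = field(default_factory=dict)
    easv_coverage: dict[str, float] = field(default_factory=dict)
    module_abundance: pd.DataFrame | None = None
    degree_profile: pd.DataFrame | None = None

    # -- convenience accessors -------------------------------------------
    def bsasv_union(self) -> set[str]:
        out: set[str] = set()
        for kr in self.kingdoms.values():
            out |= union(kr.bsasv)
        return out

    def classification_frame(self) -> pd.DataFrame:
        frames = [classification_frame(kr.classification) for kr in self.kingdoms.values()]
        return pd.concat(frames) if frames else pd.DataFrame()

    def module_counts(self) -> dict[str, int]:
        out = {}
        for t, net in self.type_networks.items():
            out[t] = len(net.modules())
        if self.pooled_network is not None:
            out["all"] = len(self.pooled_network.modules())
        return out

    def summary(self) -> str:
        lines = [
            f"Bioturbation response analysis (bioturb {__version__})",
            f"config hash {self.config.hash()}, seed {self.config.seed}",
            f"samples: {len(self.meta)}",
            "",
        ]
        for k, kr in self.kingdoms.items():
            per_type = {t: len(s) for t, s in sorted(kr.bsasv.items())}
            lines += [
                f"[{k}]",
                f"  pASV: {len(kr.pasv)}   iASV: {len(union(kr.iasv))}   "
                f"brASV: {len(union(kr.brasv))}   bsASV: {len(union(kr.bsasv))} {per_type}",
                f"  common dispersion: {kr.dispersion:.4f}   "
                f"differential (FDR<{self.config.fdr_alpha}): {len(kr.differential)}",
                f"  bioturbation effect size: {kr.effect_size_pct:.2f}% of sequences",
            ]
        if self.mic is not None:
            counts = {a: len(self.easv.get(a, set())) for a in self.mic.columns}
            strong = {a: len(self.strong_easv.get(a, set())) for a in self.mic.columns}
            lines += ["", f"eASV counts (MIC>={self.config.mic_threshold}): {counts}",
                      f"strong eASV (MIC>={self.config.mic_strong_threshold}): {strong}"]
        if self.pooled_network is not None:
            lines += [
                "",
                f"modules: {self.module_counts()}",
                f"bsModules (top {self.config.top_k_modules}, share>="
                f"{self.config.bsmodule_min_share}): {sorted(self.bsmodules)}",
            ]
        if self.effect_intensity:
            fmt = {a: (f"{v:.2f}%" if np.isfinite(v) else "NA")
                   for a, v in self.effect_intensity.items()}
            lines.append(f"effect intensity (bsASV share of eASVs): {fmt}")
        if self.easv_coverage:
            fmt = {a: (f"{v:.1f}%" if np.isfinite(v) else "NA")
                   for a, v in self.easv_coverage.items()}
            lines.append(f"eASV coverage by bsModules: {fmt}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the result tables as TSV with a version/config header."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# bioturb {__version__} config={self.config.hash()} seed={self.config.seed}\n"

        def dump(frame: pd.DataFrame, name: str, index=True) -> None:
            with open(outdir / name, "w", encoding="utf-8") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=index)

        dump(self.classification_frame(), "classification.tsv")
        eff = pd.DataFrame(
            [
                {"kingdom": k, "effect_size_pct": kr.effect_size_pct}
                for k, kr in self.kingdoms.items()
            ]
        )
        dump(eff, "effect_size.tsv", index=False)
        if self.mic is not None:
            dump(self.mic, "mic.tsv")
        if self.effect_intensity:
            dump(
                pd.DataFrame(
                    [{"activity": a, "intensity_pct": v}
                     for a, v in self.effect_intensity.items()]
                ),
                "effect_intensity.tsv",
                index=False,
            )
        if self.easv_coverage:
            dump(
                pd.DataFrame(
                    [{"activity": a, "coverage_pct": v}
                     for a, v in self.easv_coverage.items()]
                ),
                "coverage.tsv",
                index=False,
            )
        if self.pooled_network is not None:
            edges = pd.DataFrame(
                self.pooled_network.edges, columns=["source", "target", "rho"]
            )
            dump(edges, "edges.tsv", index=False)
            mods = pd.DataFrame(
                sorted(self.pooled_network.module_of.items()),
                columns=["asv_id", "module"],
            )
            dump(mods, "modules.tsv", index=False)
            dump(pd.DataFrame(
                [{"module": m, "is_bsmodule": m in self.bsmodules}
                 for m in self.pooled_network.top_modules(self.config.top_k_modules)]
            ), "bsmodules.tsv", index=False)
        if self.module_abundance is not None:
            dump(self.module_abundance, "module_abundance.tsv", index=False)
        if self.degree_profile is not None:
            dump(self.degree_profile, "degree_profile.tsv")
        with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")

    def plot_degree_abundance(self, ax=None):
        """Degree vs mean CPM scatter with responsive taxa highlighted."""
        import matplotlib.pyplot as plt

        if self.degree_profile is None:
            raise ValueError("no network/degree profile in results")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        prof = self.degree_profile
        base = prof[~prof["highlighted"]]
        hi = prof[prof["highlighted"]]
        ax.scatter(base["degree"], base["mean_cpm"], s=8, c="0.7", label="all ASVs")
        ax.scatter(hi["degree"], hi["mean_cpm"], s=14, c="crimson", label="bsASV")
        ax.set_xlabel("co-occurrence degree")
        ax.set_ylabel("mean CPM")
        ax.set_yscale("symlog")
        ax.legend(frameon=False)
        return ax


class BioturbationAnalysis:
    """Analysis model for a fermentation inoculation study.

    Parameters
    ----------
    tables : mapping of kingdom name -> CountTable
    meta : list of SampleInfo covering the tables' samples
    config : PipelineConfig, optional
    """

    def __init__(self, tables: dict[str, CountTable], meta: list[SampleInfo],
                 config: PipelineConfig | None = None):
        if not tables:
            raise ValueError("need at least one count table")
        self.config = config or PipelineConfig()
        self.tables: dict[str, CountTable] = {}
        self.meta_by_kingdom: dict[str, list[SampleInfo]] = {}
        for k, t in tables.items():
            tt, mm = align(t, meta)
            self.tables[k] = tt
            self.meta_by_kingdom[k] = mm
        self.meta = self.meta_by_kingdom[next(iter(tables))]

    @classmethod
    def from_files(cls, counts_paths: dict[str, str], metadata_path: str,
                   config: PipelineConfig | None = None) -> "BioturbationAnalysis":
        tables = {k: read_count_table(p, k) for k, p in counts_paths.items()}
        return cls(tables, read_metadata(metadata_path), config)

    @classmethod
    def from_synthetic(cls, seed: int = 0, config: PipelineConfig | None = None,
                       sim_config=None, bacteria_only: bool = False):
        """Build the model on a generated study; returns (model, truths)."""
        from .synthetic_data import generate_dataset

        data = generate_dataset(seed, config=sim_config)
        tables = data["tables"]
        if bacteria_only:
            tables = {"bacteria": tables["bacteria"]}
        model = cls(tables, data["meta"],
                    (config or PipelineConfig()).with_seed(seed))
        return model, data["truths"]

    # ------------------------------------------------------------------
    def fit(self, per_type_networks: bool = True,
            compute_mic: bool = True) -> BioturbationResults:
        cfg = self.config
        kingdoms: dict[str, KingdomResults] = {}
        mic_frames = []
        filtered_cpm_frames = []  # sample x asv, network universe
        for k, table in self.tables.items():
            meta = self.meta_by_kingdom[k]
            groups = {s.sample_id: s.mtd_type.value for s in meta}
            factors = tmm_factors(table)
            cpm_mat = cpm(table, factors)

            pasv, drivers = identify_pasv(
                table, meta,
                rho_min=cfg.pasv_rho_min, alpha=cfg.pasv_alpha,
                mantel_alpha=cfg.mantel_alpha, n_perm=cfg.n_perm,
                seed=cfg.stage_seed(f"mantel:{k}"), per_type=cfg.pasv_per_type,
            )
            ind = indval(
                table, groups, n_perm=cfg.n_perm,
                seed=cfg.stage_seed(f"indval:{k}"),
                max_combo_size=cfg.max_combo_size,
                abundance=cpm_mat.to_numpy(),
            )
            iasv = select_iasv(ind, cfg.indicator_alpha)
            dispersion = estimate_common_dispersion(table, factors, groups)
            da = nb_lrt(table, factors, groups, dispersion)
            differential = select_differential(da, cfg.fdr_alpha)
            brasv = derive_brasv(iasv, pasv)
            bsasv = derive_bsasv(brasv, differential)
            eff = effect_size(union(bsasv), table)

            filtered = filter_for_network(table)
            filt_cpm = cpm_mat.loc[filtered.asv_ids].T  # sample x asv
            filtered_cpm_frames.append(filt_cpm)
            if compute_mic:
                acts = metadata_to_frame(meta).loc[table.sample_ids, list(ACTIVITIES)]
                mic_frames.append(
                    mic_matrix(filt_cpm, acts, alpha=cfg.mic_alpha, c=cfg.mic_c)
                )
            kingdoms[k] = KingdomResults(
                kingdom=k, factors=factors, cpm=cpm_mat,
                pasv=pasv, pasv_drivers=drivers,
                indicator_results=ind, iasv=iasv, brasv=brasv, bsasv=bsasv,
                dispersion=dispersion, diffabund_results=da,
                differential=differential, effect_size_pct=eff,
                classification=[], filtered_asvs=filtered.asv_ids,
            )

        mic_all = pd.concat(mic_frames) if mic_frames else None
        if mic_all is not None:
            easv, strong = identify_easv(
                mic_all, cfg.mic_threshold, cfg.mic_strong_threshold
            )
        else:
            easv, strong = {}, {}

        for k, kr in kingdoms.items():
            kr.classification = build_classification(
                k, self.tables[k].asv_ids, kr.pasv, kr.pasv_drivers,
                kr.indicator_results, kr.iasv, kr.brasv, kr.bsasv,
                mic=mic_all, easv=easv, strong=strong,
            )

        pooled_cpm = pd.concat(filtered_cpm_frames, axis=1)
        pooled_net = detect_modules(
            build_network(pooled_cpm, cfg.network_rho_min, cfg.network_p_max),
            seed=cfg.stage_seed("modules"),
        )
        type_nets: dict[str, CooccurrenceNetwork] = {}
        if per_type_networks:
            mf = metadata_to_frame(self.meta)
            for t in sorted(mf["mtd_type"].unique()):
                samp = list(mf.index[mf["mtd_type"] == t])
                sub = pooled_cpm.loc[samp]
                sub = sub.loc[:, sub.sum(axis=0) > 0]
                type_nets[t] = detect_modules(
                    build_network(sub, cfg.network_rho_min, cfg.network_p_max),
                    seed=cfg.stage_seed(f"modules:{t}"),
                )

        bs_union: set[str] = set()
        for kr in kingdoms.values():
            bs_union |= union(kr.bsasv)
        bsmods = identify_bsmodules(
            pooled_net, bs_union, cfg.top_k_modules, cfg.bsmodule_min_share
        )
        intensity = effect_intensity(bs_union, easv) if easv else {}
        coverage = (
            easv_module_coverage(easv, bsmods, pooled_net) if easv else {}
        )
        mod_abund = module_abundance(pooled_net, pooled_cpm, self.meta, by="type x phase")
        profile = degree_abundance_profile(pooled_net, pooled_cpm, highlight=bs_union)

        return BioturbationResults(
            config=cfg, meta=self.meta, kingdoms=kingdoms,
            mic=mic_all, easv=easv, strong_easv=strong,
            pooled_network=pooled_net, type_networks=type_nets,
            bsmodules=bsmods, effect_intensity=intensity,
            easv_coverage=coverage, module_abundance=mod_abund,
            degree_profile=profile,
        )


__all__ = [
    "BioturbationAnalysis",
    "BioturbationResults",
    "KingdomResults",
    "profile_summary",
]
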