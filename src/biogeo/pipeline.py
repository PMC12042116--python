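"""End-to-end pipeline: synthesize-or-load tables, rarefy, then run every
analysis stage (alpha diversity and latitude regressions, distance decay,
Mantel, region permutation tests, NMDS, CCA/VPA, taxa-environment
correlations, SPEC-OCCU specialists, per-region co-occurrence networks),
writing TSV outputs and a checksum manifest.

All randomness flows from one root seed through named substreams
(:func:`biogeo._utils.stage_seed`), so each stage is reproducible on its
own and two runs with the same config produce byte-identical files.
Stage failures are recorded in the manifest and later independent stages
still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, network, ordination, permtests, spatial, specocc, synth, tables
from ._utils import BiogeoError, stage_seed

log = logging.getLogger("biogeo")

FLOAT_FMT = "%.10g"

#: taxa kept in the taxa-environment correlation table, per domain
TOP_N_TAXA = {"bacteria": 10, "archaea": 5, "fungi": 5}


@dataclass(frozen=True)
class RunConfig:
    """One config object driving the whole pipeline.

    Either ``input_counts``/``input_metadata``/``input_taxonomy`` point at
    existing TSVs, or ``synth`` parameterizes the generator. Thresholds
    default to the standard analysis values: specialist 0.7, network
    |rho| > 0.7 / adjusted p < 0.05 / prevalence > 0.5.
    """

    outdir: str = "biogeo_out"
    seed: int = 0
    synth: synth.SynthConfig | None = None
    input_counts: dict[str, str] = field(default_factory=dict)  # domain -> path
    input_metadata: str | None = None
    input_taxonomy: str | None = None
    rarefaction_depth: int | None = None  # None => min sample total per domain
    n_perm: int = 999
    specialist_threshold: float = 0.7
    network_r_threshold: float = 0.7
    network_alpha: float = 0.05
    network_prevalence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("specialist_threshold", "network_r_threshold",
                     "network_alpha", "network_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise BiogeoError(f"{name} must be within [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth_cfg = None
        if "synth" in raw:
            s = dict(raw.pop("synth"))
            for key in ("lat_range", "lon_range"):
                if key in s:
                    s[key] = tuple(s[key])
            synth_cfg = synth.SynthConfig(**s)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BiogeoError(f"unknown config keys: {sorted(unknown)}")
        return cls(synth=synth_cfg, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.rows: list[tuple[str, str, str, str]] = []

    def add(self, stage: str, path: Path) -> None:
        self.rows.append((stage, str(path.relative_to(self.outdir)), _sha256(path), "ok"))

    def fail(self, stage: str, err: Exception) -> None:
        log.error("stage %s failed: %s", stage, err)
        self.rows.append((stage, "", "", f"failed: {err}"))

    def write(self) -> Path:
        path = self.outdir / "manifest.tsv"
        pd.DataFrame(self.rows, columns=["stage", "file", "sha256", "status"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )
        return path


def _write(df: pd.DataFrame, path: Path, manifest: _Manifest, stage: str,
           index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index, lineterminator="\n")
    manifest.add(stage, path)


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    if config.input_metadata is not None:
        for name, p in [("metadata", config.input_metadata),
                        ("taxonomy", config.input_taxonomy),
                        *[(f"counts[{d}]", p) for d, p in config.input_counts.items()]]:
            if p is None or not Path(p).exists():
                raise BiogeoError(f"input file missing before any computation: {name} = {p}")
        meta = tables.read_metadata(config.input_metadata)
        if "region" not in meta.columns:
            meta = tables.assign_regions(meta)
        counts = {d: tables.read_count_table(p) for d, p in config.input_counts.items()}
        tax = tables.read_taxonomy(config.input_taxonomy)
        return meta, counts, tax
    scfg = config.synth or synth.SynthConfig(seed=config.seed)
    log.info("synthesizing dataset (seed=%d)", scfg.seed)
    meta = synth.generate_metadata(scfg)
    counts = {d: synth.generate_community(scfg, meta, d) for d in scfg.n_otus_per_domain}
    tax = synth.generate_taxonomy(scfg)
    return meta, counts, tax


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage; returns the manifest (stage, file, sha256, status)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    log.info("run: seed=%d n_perm=%d outdir=%s", config.seed, config.n_perm, outdir)

    meta, counts, tax = _load_inputs(config)
    tables.write_metadata(meta, outdir / "metadata.tsv", comments=[f"seed={config.seed}"])
    manifest.add("inputs", outdir / "metadata.tsv")
    tables.write_taxonomy(tax, outdir / "taxonomy.tsv")
    manifest.add("inputs", outdir / "taxonomy.tsv")

    geo = spatial.haversine_matrix(meta)
    tables.write_distance_matrix(geo, outdir / "geo_km.tsv")
    manifest.add("geography", outdir / "geo_km.tsv")
    regions = meta["region"]

    ddr_rows, mantel_rows, vpa_rows = [], [], []
    for domain, raw in counts.items():
        dom_seed = lambda stage: stage_seed(config.seed, f"{stage}:{domain}")

        # rarefaction
        stage = f"rarefy:{domain}"
        try:
            depth = config.rarefaction_depth or int(raw.sum(axis=1).min())
            log.info("%s: depth=%d", stage, depth)
            rare = tables.rarefy(raw, depth, dom_seed("rarefy"))
            tables.write_count_table(rare, outdir / f"rarefied_{domain}.tsv",
                                     comments=[f"seed={config.seed}", f"depth={depth}"])
            manifest.add(stage, outdir / f"rarefied_{domain}.tsv")
        except Exception as e:  # noqa: BLE001 - stage isolation
            manifest.fail(stage, e)
            continue
        rel = tables.relative_abundance(rare)

        # alpha diversity + latitude regression + region comparisons
        stage = f"alpha:{domain}"
        try:
            alpha = diversity.alpha_diversity(rare)
            _write(alpha, outdir / f"alpha_{domain}.tsv", manifest, stage)
            fits = spatial.diversity_vs_latitude(alpha, meta)
            lat_df = pd.DataFrame([
                {"metric": m, "slope": f.slope, "intercept": f.intercept,
                 "r_squared": f.r_squared, "p_value": f.p_value}
                for m, f in fits.items()
            ])
            _write(lat_df, outdir / f"diversity_vs_latitude_{domain}.tsv",
                   manifest, stage, index=False)
            wil = diversity.compare_regions_alpha(alpha, meta)
            _write(wil, outdir / f"alpha_region_tests_{domain}.tsv",
                   manifest, stage, index=False)
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)

        # beta diversity, DDR, Mantel
        stage = f"beta:{domain}"
        try:
            bc = diversity.bray_curtis(rare)
            tables.write_distance_matrix(bc, outdir / f"bray_curtis_{domain}.tsv")
            manifest.add(stage, outdir / f"bray_curtis_{domain}.tsv")
            fit = spatial.distance_decay(bc, geo)
            ddr_rows.append({"domain": domain, **fit.__dict__})
            mres = spatial.mantel(bc, geo, n_perm=config.n_perm, seed=dom_seed("mantel"))
            mantel_rows.append({"domain": domain, "r": mres.r, "p": mres.p,
                                "n_perm": mres.n_perm, "method": mres.method})
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)
            bc = None

        # community structure tests + NMDS
        stage = f"community_tests:{domain}"
        if bc is not None:
            try:
                tests = permtests.community_test_table(
                    bc, regions, n_perm=config.n_perm, seed=dom_seed("permtests"))
                _write(tests, outdir / f"community_tests_{domain}.tsv",
                       manifest, stage, index=False)
                nm = permtests.nmds(bc, seed=dom_seed("nmds"))
                coords = nm.coordinates.copy()
                coords["stress"] = nm.stress
                coords["converged"] = nm.converged
                _write(coords, outdir / f"nmds_{domain}.tsv", manifest, stage)
            except Exception as e:  # noqa: BLE001
                manifest.fail(stage, e)

        # constrained ordination + variation partitioning
        stage = f"ordination:{domain}"
        try:
            env_cols = ["temperature", "salinity", "pH", "NO3", "NH4", "TOC"]
            spatial_cols = ["longitude", "latitude", "depth"]
            env = meta[env_cols]
            cres = ordination.cca(rare, env, n_perm=config.n_perm, seed=dom_seed("cca"))
            _write(cres.site_scores, outdir / f"cca_sites_{domain}.tsv", manifest, stage)
            _write(cres.species_scores, outdir / f"cca_species_{domain}.tsv", manifest, stage)
            summary = pd.DataFrame([{
                "total_inertia": cres.total_inertia,
                "constrained_proportion": cres.constrained_proportion,
                "pseudo_f": cres.pseudo_f,
                "permutation_p": cres.permutation_p,
                "kept_variables": ",".join(cres.kept_variables),
            }])
            _write(summary, outdir / f"cca_summary_{domain}.tsv", manifest, stage, index=False)
            vpa = ordination.variation_partition(
                rare, env, meta[spatial_cols],
                n_perm=config.n_perm, seed=dom_seed("vpa"))
            vpa_rows.append({"domain": domain, **vpa.__dict__})
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)

        # taxa-environment correlations (split phyla, then genera)
        stage = f"taxa_env:{domain}"
        try:
            phylum = tables.aggregate_by_rank(rare, tax, "phylum", split_proteobacteria=True)
            corr_p = ordination.taxa_env_correlations(
                tables.relative_abundance(phylum), meta, top_n=TOP_N_TAXA.get(domain, 5))
            _write(corr_p, outdir / f"taxa_env_phylum_{domain}.tsv", manifest, stage, index=False)
            genus = tables.aggregate_by_rank(rare, tax, "genus")
            corr_g = ordination.taxa_env_correlations(
                tables.relative_abundance(genus), meta, top_n=TOP_N_TAXA.get(domain, 5))
            _write(corr_g, outdir / f"taxa_env_genus_{domain}.tsv", manifest, stage, index=False)
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)

        # SPEC-OCCU and specialists
        stage = f"spec_occ:{domain}"
        try:
            records = specocc.spec_occ(rel, regions)
            _write(records, outdir / f"spec_occ_{domain}.tsv", manifest, stage, index=False)
            specs = specocc.classify_specialists(
                records, config.specialist_threshold, taxonomy=tax)
            _write(specs, outdir / f"specialists_{domain}.tsv", manifest, stage, index=False)
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)

        # per-region co-occurrence networks
        stage = f"network:{domain}"
        try:
            nets = network.region_networks(
                rare, regions, tax,
                min_fraction=config.network_prevalence,
                r_threshold=config.network_r_threshold,
                alpha=config.network_alpha,
            )
            topo_rows = []
            for region, net in nets.items():
                slug = region.replace("-", "_")
                _write(net.edges, outdir / f"edges_{domain}_{slug}.tsv",
                       manifest, stage, index=False)
                network.write_graphml(net, outdir / f"network_{domain}_{slug}.graphml")
                manifest.add(stage, outdir / f"network_{domain}_{slug}.graphml")
                topo_rows.append({"region": region, **net.topology.__dict__})
            _write(pd.DataFrame(topo_rows), outdir / f"network_topology_{domain}.tsv",
                   manifest, stage, index=False)
        except Exception as e:  # noqa: BLE001
            manifest.fail(stage, e)

    if ddr_rows:
        _write(pd.DataFrame(ddr_rows), outdir / "ddr.tsv", manifest, "ddr", index=False)
    if mantel_rows:
        _write(pd.DataFrame(mantel_rows), outdir / "mantel.tsv", manifest, "mantel", index=False)
    if vpa_rows:
        _write(pd.DataFrame(vpa_rows), outdir / "vpa.tsv", manifest, "vpa", index=False)

    path = manifest.write()
    log.info("manifest written to %s", path)
    return pd.read_csv(path, sep="\t").fillna("")
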