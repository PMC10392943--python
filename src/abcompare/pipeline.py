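"""End-to-end orchestration: curate -> sites -> profiles -> geometry ->
clustering -> group statistics.

`run_compare` consumes a manifest of complexes (PDB path, chain roles,
Ab/sdAb label, optional numbering sidecar), derives per-complex binding-site
profiles, and compares the two groups metric by metric with bootstrap /
permutation statistics.  `worked_example_table` produces the side-by-side
single-pair comparison (CDR-H3 length, site sizes, interaction counts) for
one Ab and one sdAb complex.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding_site_profiles import (
    epitope_linearity,
    loop_contributions,
    framework_position_frequency,
    seven_class_composition,
)
from .interaction_engine import (
    InteractionConfig,
    binding_site,
    count_interactions,
    find_contacts,
    interactions_per_residue,
    summarize_pairs,
)
from .loop_clustering import (
    cluster_summary,
    extract_loop_records,
    greedy_cluster,
    random_overlap_null,
)
from .loop_geometry import FrameError, build_frame, orient_loop
from .resampling_stats import bootstrap_mean_diff
from .sasa_accessibility import epitope_accessibility
from .structure_model import (
    AntibodyComplex,
    CurationRules,
    annotate_regions,
    filter_dataset,
    read_complex,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the study defaults."""

    contact_cutoff: float = 4.5
    cdr_identity_cutoff: float = 0.95
    epitope_identity_cutoff: float = 0.75
    cluster_rmsd_cutoff: float = 1.5
    occupancy_floor: float = 0.05
    framework_frequency_threshold: float = 0.10
    burial_threshold: float = 0.1
    subsample_fraction: float = 0.10
    subsample_reps: int = 1000
    n_boot: int = 5000
    boot_size: int = 300
    n_perm: int = 5000
    null_reps: int = 20
    seed: int = 0
    max_resolution: float = 3.0
    antigen_mode: str = "protein"
    definition: str = "interactions"
    compute_sasa_sites: bool = False

    def curation_rules(self) -> CurationRules:
        return CurationRules(
            max_resolution=self.max_resolution,
            contact_cutoff=self.contact_cutoff,
            antigen_mode=self.antigen_mode,
        )

    def interaction_config(self) -> InteractionConfig:
        return InteractionConfig(cutoff=self.contact_cutoff)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV: pdb_path, label (Ab|sdAb), heavy, light, antigen
    (comma-separated chain ids), numbering (optional sidecar path)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"pdb_path", "label", "heavy", "antigen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return df


def load_manifest_complexes(
    manifest: pd.DataFrame, base_dir: str | Path = "."
) -> tuple[list[tuple[AntibodyComplex, str]], list[tuple[str, str]]]:
    """Read and annotate every manifest entry; failures are logged, not fatal."""
    base = Path(base_dir)
    loaded: list[tuple[AntibodyComplex, str]] = []
    failures: list[tuple[str, str]] = []
    for _, row in manifest.iterrows():
        path = base / row["pdb_path"]
        chain_map = {row["heavy"]: "heavy"}
        if row.get("light"):
            chain_map[row["light"]] = "light"
        for cid in row["antigen"].split(","):
            chain_map[cid.strip()] = "antigen"
        try:
            cx = read_complex(
                path, chain_map, numbering=(row.get("numbering") or None)
            )
            annotate_regions(cx)
            loaded.append((cx, row["label"]))
        except Exception as exc:  # noqa: BLE001 - per-complex failures are logged
            logger.warning("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
    return loaded, failures


@dataclass
class ComplexProfile:
    """Everything measured on one complex."""

    pdb_id: str
    label: str
    is_sdab: bool
    cdr_h3_length: int
    paratope_size: dict[str, int]
    epitope_size: dict[str, int]
    n_interactions: int
    interactions_per_paratope_residue: float
    linear_pct: dict[str, float]
    accessibility: float | None
    cdr_fraction: float
    cdr_h3_paratope_residues: int
    cdr_h3_interactions: int
    paratope_composition: dict[str, float]
    epitope_composition: dict[str, float]
    framework_positions: set


def profile_complex(
    cx: AntibodyComplex,
    label: str,
    config: RunConfig | None = None,
    with_accessibility: bool = True,
) -> ComplexProfile:
    config = config or RunConfig()
    icfg = config.interaction_config()
    contacts = find_contacts(cx, config=icfg)
    pairs = summarize_pairs(contacts)
    interacting = [p for p in pairs if p.classification == "interaction"]
    dist_site = binding_site(cx, "distance", config=icfg, contacts=contacts)
    int_site = binding_site(cx, "interactions", config=icfg, contacts=contacts)
    sites = {"distance": dist_site, "interactions": int_site}
    if config.compute_sasa_sites:
        sites["sasa"] = binding_site(cx, "sasa")

    profile = loop_contributions(cx, int_site, interacting)
    ipr = (
        interactions_per_residue(int_site, interacting) if int_site.paratope else 0.0
    )
    linear_pct = {}
    for name, site in sites.items():
        if site.epitope:
            _, pct = epitope_linearity(site.epitope)
            linear_pct[name] = pct
    accessibility = None
    if with_accessibility and int_site.epitope:
        accessibility = epitope_accessibility(cx.antigen_residues(), int_site.epitope)

    total, _ = count_interactions(interacting)
    epi_comp = (
        seven_class_composition(int_site.epitope).fractions if int_site.epitope else {}
    )
    return ComplexProfile(
        pdb_id=cx.pdb_id,
        label=label,
        is_sdab=cx.is_sdab,
        cdr_h3_length=len(cx.cdr_residues("CDR3", "heavy")),
        paratope_size={name: len(site.paratope) for name, site in sites.items()},
        epitope_size={name: len(site.epitope) for name, site in sites.items()},
        n_interactions=total,
        interactions_per_paratope_residue=ipr,
        linear_pct=linear_pct,
        accessibility=accessibility,
        cdr_fraction=profile.cdr_fraction,
        cdr_h3_paratope_residues=profile.per_loop_residues.get("CDR-H3", 0),
        cdr_h3_interactions=profile.per_loop_interactions.get("CDR-H3", 0),
        paratope_composition=profile.composition.fractions if int_site.paratope else {},
        epitope_composition=epi_comp,
        framework_positions=profile.framework_positions,
    )


def profiles_table(profiles: list[ComplexProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "pdb_id": p.pdb_id,
            "label": p.label,
            "is_sdab": p.is_sdab,
            "cdr_h3_length": p.cdr_h3_length,
            "n_interactions": p.n_interactions,
            "interactions_per_paratope_residue": p.interactions_per_paratope_residue,
            "accessibility": p.accessibility,
            "cdr_fraction": p.cdr_fraction,
            "cdr_h3_paratope_residues": p.cdr_h3_paratope_residues,
            "cdr_h3_interactions": p.cdr_h3_interactions,
        }
        for name, v in p.paratope_size.items():
            row[f"paratope_size_{name}"] = v
        for name, v in p.epitope_size.items():
            row[f"epitope_size_{name}"] = v
        for name, v in p.linear_pct.items():
            row[f"linear_pct_{name}"] = v
        for cls, v in p.paratope_composition.items():
            row[f"paratope_{cls}"] = v
        for cls, v in p.epitope_composition.items():
            row[f"epitope_{cls}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


#: metrics compared between the sdAb and Ab groups (sdAb minus Ab)
COMPARED_METRICS = (
    "cdr_h3_length",
    "paratope_size_distance",
    "paratope_size_interactions",
    "epitope_size_distance",
    "epitope_size_interactions",
    "linear_pct_distance",
    "linear_pct_interactions",
    "accessibility",
    "interactions_per_paratope_residue",
    "cdr_fraction",
)


def compare_groups(
    table: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Bootstrap/permutation comparison of every metric, sdAb minus Ab."""
    config = config or RunConfig()
    sd = table[table["label"] == "sdAb"]
    ab = table[table["label"] == "Ab"]
    if sd.empty or ab.empty:
        raise ValueError("need both sdAb and Ab complexes to compare groups")
    rows = []
    rng = np.random.default_rng(config.seed)
    for metric in COMPARED_METRICS:
        if metric not in table.columns:
            continue
        a = sd[metric].dropna().to_numpy(dtype=float)
        b = ab[metric].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        res = bootstrap_mean_diff(
            a, b, n_boot=config.n_boot, boot_size=config.boot_size,
            n_perm=config.n_perm, seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "metric": metric,
                "mean_sdAb": float(a.mean()),
                "mean_Ab": float(b.mean()),
                "mean_diff": res.mean_diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "significant": res.significant,
                "n_sdAb": int(a.size),
                "n_Ab": int(b.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    profiles: pd.DataFrame
    comparisons: pd.DataFrame
    cluster_summaries: dict[str, dict]
    orientation: pd.DataFrame
    framework_frequency: list
    failures: list[tuple[str, str]]
    config: RunConfig


def run_compare(
    complexes: list[tuple[AntibodyComplex, str]],
    config: RunConfig | None = None,
    curate: bool = False,
) -> RunReport:
    """Full group comparison over pre-loaded, region-annotated complexes."""
    config = config or RunConfig()
    if not complexes:
        raise ValueError("no complexes to analyse")
    failures: list[tuple[str, str]] = []
    if curate:
        kept, log = filter_dataset([cx for cx, _ in complexes], config.curation_rules())
        kept_ids = {id(cx) for cx in kept}
        failures.extend(log)
        complexes = [(cx, lab) for cx, lab in complexes if id(cx) in kept_ids]

    profiles = []
    dataset = []
    for cx, label in complexes:
        try:
            prof = profile_complex(cx, label, config)
        except Exception as exc:  # noqa: BLE001
            logger.warning("profiling failed for %s: %s", cx.pdb_id, exc)
            failures.append((cx.pdb_id, f"profiling: {exc}"))
            continue
        profiles.append(prof)
        dataset.append((cx, label))
    table = profiles_table(profiles)
    comparisons = compare_groups(table, config)

    # loop clustering with the random-overlap null
    loops = [
        rec
        for cx, label in dataset
        for rec in extract_loop_records(cx, label)
    ]
    cluster_summaries: dict[str, dict] = {}
    rng = np.random.default_rng(config.seed + 1)
    for loop_name in ("CDR-H1", "CDR-H2", "CDR-H3"):
        subset = [r for r in loops if r.loop == loop_name]
        if not subset:
            continue
        cs = greedy_cluster(subset, cutoff=config.cluster_rmsd_cutoff)
        summary = cluster_summary(cs)
        null_mean, null_sd = random_overlap_null(
            [len(c) for c in cs.clusters],
            [r.label for r in subset],
            reps=config.null_reps,
            seed=int(rng.integers(2**31)),
        )
        summary["null_overlap_mean"] = null_mean
        summary["null_overlap_sd"] = null_sd
        cluster_summaries[loop_name] = summary

    # CDR-H3 orientation descriptors
    orient_rows = []
    for cx, label in dataset:
        try:
            frame = build_frame(cx.heavy)
            lo = orient_loop(cx.heavy, frame)
        except FrameError as exc:
            logger.info("orientation skipped for %s: %s", cx.pdb_id, exc)
            continue
        orient_rows.append(
            {
                "pdb_id": cx.pdb_id,
                "label": label,
                "loop_length": lo.loop_length,
                "rho": lo.rho,
                "theta": lo.theta,
                "phi": lo.phi,
                "compactness": lo.compactness,
            }
        )
    orientation = pd.DataFrame(orient_rows)

    fw_dataset = []
    for (cx, label), prof in zip(dataset, profiles):
        if label == "sdAb":
            site_profile = type("P", (), {"framework_positions": prof.framework_positions})
            fw_dataset.append((cx, site_profile))
    fw_freq = (
        framework_position_frequency(fw_dataset, config.framework_frequency_threshold)
        if fw_dataset
        else []
    )

    return RunReport(
        profiles=table,
        comparisons=comparisons,
        cluster_summaries=cluster_summaries,
        orientation=orientation,
        framework_frequency=fw_freq,
        failures=failures,
        config=config,
    )


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    report.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    if not report.orientation.empty:
        report.orientation.to_csv(out / "orientation.tsv", sep="\t", index=False)
    cluster_df = pd.DataFrame(report.cluster_summaries).T
    if not cluster_df.empty:
        cluster_df.to_csv(out / "clusters.tsv", sep="\t")
    provenance = dataclasses.asdict(report.config)
    provenance["package_version"] = __version__
    provenance["n_failures"] = len(report.failures)
    provenance["failures"] = [list(f) for f in report.failures]
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance))


def worked_example_table(
    ab: AntibodyComplex, sdab: AntibodyComplex, config: RunConfig | None = None
) -> pd.DataFrame:
    """Side-by-side comparison of one Ab and one sdAb complex.

    Reports CDR-H3 length, interactions-defined paratope and epitope sizes,
    total interactions, interactions per paratope residue, and the CDR-H3
    contribution to the paratope.
    """
    config = config or RunConfig()
    rows = {}
    for name, cx in (("Ab", ab), ("sdAb", sdab)):
        prof = profile_complex(cx, name, config, with_accessibility=False)
        rows[name] = {
            "pdb_id": prof.pdb_id,
            "cdr_h3_length": prof.cdr_h3_length,
            "paratope_size": prof.paratope_size["interactions"],
            "epitope_size": prof.epitope_size["interactions"],
            "total_interactions": prof.n_interactions,
            "interactions_per_paratope_residue": round(
                prof.interactions_per_paratope_residue, 1
            ),
            "cdr_h3_paratope_residues": prof.cdr_h3_paratope_residues,
        }
    return pd.DataFrame(rows)


def run_worked_example(
    ab_pdb: str | Path,
    sdab_pdb: str | Path,
    ab_chain_map: dict[str, str],
    sdab_chain_map: dict[str, str],
    ab_numbering: str | Path | None = None,
    sdab_numbering: str | Path | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """The worked-example comparison on user-supplied coordinate files."""
    ab = annotate_regions(read_complex(ab_pdb, ab_chain_map, ab_numbering))
    sdab = annotate_regions(read_complex(sdab_pdb, sdab_chain_map, sdab_numbering))
    return worked_example_table(ab, sdab, config)
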