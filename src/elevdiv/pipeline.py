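"""End-to-end pipeline: ingest/simulate -> ranges -> diversity -> Rapoport -> barcode.

One :class:`PipelineConfig` (YAML-loadable) drives every stage; one seed
governs the simulator and every bootstrap, so identical config + seed gives
a byte-identical summary JSON (timestamps excluded).  Machine-readable
outputs are CSV/JSON files in the configured output directory; logging goes
to stderr only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import barcode as bc
from . import diversity as dv
from . import rapoport as rp
from .occurrence_io import (
    AltitudeAreaSpec,
    ElevationBandSpec,
    pool_by_area,
    ranges_to_frame,
    read_occurrences,
    read_sites,
    species_ranges,
    vectors_to_frame,
    write_occurrences,
    write_sites,
)
from .synthetic import CommunityParams, simulate_community

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report", "share_pct"]


def share_pct(part: float, whole: float) -> float:
    """Percentage of ``part`` in ``whole``, rounded to the two decimals used
    in report tables (e.g. 43 of 59 -> 72.88)."""
    return round(100.0 * part / whole, 2)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is true (occurrences come from the synthetic
    community generator) or ``occurrence_path``/``sites_path`` point at CSV
    tables.  The barcode stage runs only when ``fasta_path`` is given or
    ``simulate_barcodes`` is true.
    """

    output_dir: str = "elevdiv_out"
    simulate: bool = True
    occurrence_path: str | None = None
    sites_path: str | None = None
    fasta_path: str | None = None
    simulate_barcodes: bool = False
    community: CommunityParams = field(default_factory=CommunityParams)
    bands: ElevationBandSpec = field(default_factory=ElevationBandSpec)
    areas: AltitudeAreaSpec = field(default_factory=AltitudeAreaSpec)
    q_orders: tuple[int, ...] = (0, 1, 2)
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    methods: tuple[str, ...] = rp.METHODS
    exclude_singletons: bool = True
    barcode_n_boot: int = 100
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "community" in kwargs and isinstance(kwargs["community"], dict):
            comm = dict(kwargs["community"])
            if "domain_m" in comm:
                comm["domain_m"] = tuple(comm["domain_m"])
            kwargs["community"] = CommunityParams(**comm)
        if "bands" in kwargs and isinstance(kwargs["bands"], dict):
            kwargs["bands"] = ElevationBandSpec(**kwargs["bands"])
        if "areas" in kwargs and isinstance(kwargs["areas"], dict):
            a = dict(kwargs["areas"])
            for key in ("breaks_m", "labels"):
                if key in a:
                    a[key] = tuple(a[key])
            kwargs["areas"] = AltitudeAreaSpec(**a)
        for key in ("q_orders", "methods"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["community"] = self.community.to_dict()
        return d


@dataclass
class RunReport:
    """Consolidated, JSON-serializable pipeline result."""

    totals: dict
    range_summary: dict
    diversity: list[dv.HillEstimate]
    coverage: dict[str, float]
    rapoport: dict[str, rp.MethodResult]
    barcode: dict | None
    provenance: dict

    def to_dict(self, include_timestamp: bool = True) -> dict:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        return {
            "totals": self.totals,
            "range_summary": self.range_summary,
            "diversity": [dataclasses.asdict(h) for h in self.diversity],
            "coverage": self.coverage,
            "rapoport": {
                m: _method_dict(res) for m, res in sorted(self.rapoport.items())
            },
            "barcode": self.barcode,
            "provenance": prov,
        }


def _method_dict(res: rp.MethodResult) -> dict:
    d = {
        "method": res.method,
        "x": res.x,
        "y": res.y,
        "species_counts": res.species_counts,
        "fit": dataclasses.asdict(res.fit),
        "supports_rapoport": res.supports_rapoport,
    }
    if res.quadratic_fit is not None:
        d["quadratic_fit"] = dataclasses.asdict(res.quadratic_fit)
        d["unimodal"] = res.unimodal
    return d


def _seed_for(base: int, stage: str) -> int:
    """Stable per-stage bootstrap seed derived from the run seed (< 2**31)."""
    h = np.uint32(2166136261)
    for ch in stage:
        h = np.uint32((int(h) ^ ord(ch)) * 16777619 & 0xFFFFFFFF)
    return int((np.uint32(base) ^ h) & 0x7FFFFFFF)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages in dependency order, writing outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: data (simulate or ingest) ---------------------------------
    if config.simulate:
        community = dataclasses.replace(config.community, seed=config.seed)
        sites, truth, records = simulate_community(community)
        pd.DataFrame(
            [
                {
                    "species_id": t.species_id,
                    "true_low_m": t.true_range_m[0],
                    "true_high_m": t.true_range_m[1],
                    "mean_abundance": t.mean_abundance,
                }
                for t in truth
            ]
        ).to_csv(out / "ground_truth.csv", index=False)
    else:
        if not (config.sites_path and config.occurrence_path):
            raise ValueError(
                "ingest stage: sites_path and occurrence_path are required "
                "when simulate is false"
            )
        sites = read_sites(config.sites_path)
        records = read_occurrences(config.occurrence_path, sites)
    write_sites(sites, out / "sites.csv")
    write_occurrences(records, out / "occurrences.csv")

    n_individuals = sum(r.count for r in records)
    species_totals: dict[str, int] = {}
    for r in records:
        species_totals[r.species_id] = species_totals.get(r.species_id, 0) + r.count
    n_species = len(species_totals)
    n_singletons = sum(1 for v in species_totals.values() if v == 1)
    dominant = max(species_totals, key=species_totals.get)
    totals = {
        "n_individuals": n_individuals,
        "n_species": n_species,
        "n_singleton_species": n_singletons,
        "dominant_species": dominant,
        "dominant_share_pct": share_pct(species_totals[dominant], n_individuals),
    }

    # --- stage: ranges ----------------------------------------------------
    ranges = species_ranges(records, exclude_singletons=config.exclude_singletons)
    ranges_to_frame(ranges).to_csv(out / "species_ranges.csv", index=False)
    sizes = np.array([r.range_size_m for r in ranges])
    range_summary = {
        "n_representative_species": len(ranges),
        "mean_range_m": round(float(sizes.mean()), 2),
        "min_range_m": round(float(sizes.min()), 2),
        "max_range_m": round(float(sizes.max()), 2),
        "pct_ranges_below_1000m": share_pct(float(np.sum(sizes < 1000.0)), len(ranges)),
    }

    # --- stage: diversity -------------------------------------------------
    vectors = pool_by_area(records, config.areas)
    vectors = [v for v in vectors if v.n > 0]
    vectors_to_frame(vectors).to_csv(out / "abundance_vectors.csv", index=False)
    estimates: list[dv.HillEstimate] = []
    coverage: dict[str, float] = {}
    for vec in vectors:
        coverage[vec.assemblage_id] = round(dv.sample_coverage(vec), 4)
        for q in config.q_orders:
            estimates.append(
                dv.estimate_hill(
                    vec,
                    q,
                    n_boot=config.n_boot,
                    seed=_seed_for(config.seed, f"hill-{vec.assemblage_id}-{q}"),
                )
            )
    pd.DataFrame([dataclasses.asdict(h) for h in estimates]).to_csv(
        out / "diversity.csv", index=False
    )
    curves = dv.completeness_curves(vectors)
    pd.DataFrame(
        [
            {"assemblage_id": c.assemblage_id, "m": m, "coverage": cov}
            for c in curves
            for m, cov in zip(c.sizes, c.coverage)
        ]
    ).to_csv(out / "completeness_curves.csv", index=False)

    # --- stage: Rapoport tests --------------------------------------------
    results = rp.run_all_methods(
        ranges, bands=config.bands, alpha=config.alpha, methods=config.methods
    )
    for method, res in results.items():
        pd.DataFrame(
            {"x": res.x, "mean_range_m": res.y, "n_species": res.species_counts}
        ).to_csv(out / f"rapoport_{method}.csv", index=False)
    with open(out / "rapoport_summary.json", "w") as fh:
        json.dump(
            {m: _method_dict(res) for m, res in sorted(results.items())}, fh, indent=2
        )

    # --- stage: barcode (optional) ----------------------------------------
    barcode_block: dict | None = None
    if config.fasta_path or config.simulate_barcodes:
        if config.fasta_path:
            aln = bc.read_fasta(config.fasta_path)
        else:
            aln = bc.simulate_barcodes(
                n_species=10,
                seqs_per_species=3,
                seed=_seed_for(config.seed, "barcodes"),
            )
            bc.write_fasta(aln, out / "barcodes.fasta")
        tree = bc.bootstrap_supports(
            aln,
            n_boot=config.barcode_n_boot,
            seed=_seed_for(config.seed, "barcode-boot"),
        )
        with open(out / "nj_tree.nwk", "w") as fh:
            fh.write(tree.as_newick() + "\n")
        bc.write_phylip_matrix(bc.k2p_matrix(aln), out / "k2p_matrix.phy")
        report = bc.species_monophyly(tree, aln.species_labels)
        pd.DataFrame(
            [
                {"species": sp, **info}
                for sp, info in sorted(report.per_species.items())
            ]
        ).to_csv(out / "monophyly.csv", index=False)
        barcode_block = {
            "n_sequences": len(aln.records),
            "n_species": report.n_species,
            "n_monophyletic": report.n_monophyletic,
            "monophyly_pct": round(report.overall_pct, 2),
            "n_bootstrap_replicates": tree.n_replicates_used,
        }
    else:
        logger.info("barcode stage skipped (no FASTA configured)")

    report_obj = RunReport(
        totals=totals,
        range_summary=range_summary,
        diversity=estimates,
        coverage=coverage,
        rapoport=results,
        barcode=barcode_block,
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config": config.to_dict(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    with open(out / "report.json", "w") as fh:
        fh.write(render_report(report_obj, "json"))
    if config.make_plots:
        _make_plots(out, vectors, curves, results, config)
    return report_obj


def render_report(report: RunReport, format: str = "text") -> str:
    """Render a run report as ``json``, ``markdown`` or ``text``.

    Rendering is deterministic (sorted keys, fixed precision mirroring the
    field's reporting conventions: diversity to 1 decimal, ranges to 2,
    R^2 to 4) and idempotent; timestamps are excluded so identical runs
    render identically.
    """
    if format == "json":
        return json.dumps(
            report.to_dict(include_timestamp=False), indent=2, sort_keys=True
        )
    if format not in ("text", "markdown"):
        raise ValueError(
            f"unknown report format {format!r}; choose from json, markdown, text"
        )
    md = format == "markdown"
    lines: list[str] = []
    h = (lambda s: f"## {s}") if md else (lambda s: s.upper())
    lines.append(h("Totals"))
    for k, v in report.totals.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(h("Species ranges"))
    for k, v in report.range_summary.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(h("Alpha diversity (per altitude area)"))
    if md:
        lines.append("| area | q | empirical | asymptotic | 95% CI | n |")
        lines.append("|---|---|---|---|---|---|")
        for e in report.diversity:
            lines.append(
                f"| {e.assemblage_id} | {e.q} | {e.empirical:.1f} | "
                f"{e.asymptotic:.1f} | [{e.ci_low:.1f}, {e.ci_high:.1f}] | {e.n} |"
            )
    else:
        for e in report.diversity:
            lines.append(
                f"- {e.assemblage_id} q={e.q}: empirical {e.empirical:.1f}, "
                f"asymptotic {e.asymptotic:.1f} "
                f"[{e.ci_low:.1f}, {e.ci_high:.1f}], n={e.n}"
            )
    lines.append("")
    lines.append(h("Sample coverage"))
    for area, cov in sorted(report.coverage.items()):
        lines.append(f"- {area}: {cov:.3f}")
    lines.append("")
    lines.append(h("Rapoport tests"))
    for method, res in sorted(report.rapoport.items()):
        lines.append(h(method) if not md else f"### {method}")
        if md:
            lines.append("| slope | R2 | p | n | verdict |")
            lines.append("|---|---|---|---|---|")
            lines.append(
                f"| {res.fit.slope:.4f} | {res.fit.r_squared:.4f} | "
                f"{res.fit.p_value:.4g} | {res.fit.n_points} | "
                f"{res.supports_rapoport} |"
            )
        else:
            lines.append(
                f"- slope {res.fit.slope:.4f}, R2 {res.fit.r_squared:.4f}, "
                f"p {res.fit.p_value:.4g}, n {res.fit.n_points}, "
                f"verdict {res.supports_rapoport}"
            )
        if res.quadratic_fit is not None:
            lines.append(
                f"- parabolic fit: R2 {res.quadratic_fit.r_squared:.4f}, "
                f"unimodal {res.unimodal}"
            )
    if report.barcode is not None:
        lines.append("")
        lines.append(h("Barcode delimitation"))
        for k, v in report.barcode.items():
            lines.append(f"- {k}: {v}")
    else:
        lines.append("")
        lines.append(h("Barcode delimitation"))
        lines.append("- skipped (no FASTA input)")
    return "\n".join(lines) + "\n"


def _make_plots(out: Path, vectors, curves, results, config: PipelineConfig) -> None:
    """Optional figures: completeness curves, rarefaction panels, four-panel
    Rapoport summary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.plot(c.sizes, c.coverage, label=c.assemblage_id)
    ax.set_xlabel("number of individuals")
    ax.set_ylabel("sample coverage")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "completeness.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(config.q_orders), figsize=(4 * len(config.q_orders), 3.5))
    axes = np.atleast_1d(axes)
    for ax, q in zip(axes, config.q_orders):
        for vec in vectors:
            curve = dv.rarefaction_curve(vec, q)
            s = np.array(curve.sizes)
            e = np.array(curve.estimates)
            interp = s <= vec.n
            ax.plot(s[interp], e[interp], "-", label=vec.assemblage_id)
            ax.plot(s[~interp], e[~interp], "--", color=ax.lines[-1].get_color())
        ax.set_title(f"q = {q}")
        ax.set_xlabel("individuals")
    axes[0].set_ylabel("effective species")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "rarefaction.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (method, res) in zip(axes.ravel(), sorted(results.items())):
        ax.scatter(res.x, res.y, s=12)
        xs = np.linspace(min(res.x), max(res.x), 50)
        ax.plot(xs, res.fit.slope * xs + res.fit.intercept, "r-", lw=1)
        if res.quadratic_fit is not None:
            ax.plot(xs, np.polyval(res.quadratic_fit.coefficients, xs), "g--", lw=1)
        ax.set_title(f"{method} (R2={res.fit.r_squared:.3f})", fontsize=9)
        ax.set_xlabel("elevation / midpoint (m)")
        ax.set_ylabel("range size (m)")
    fig.tight_layout()
    fig.savefig(out / "rapoport_methods.png", dpi=120)
    plt.close(fig)
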