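"""End-to-end orchestration: simulate -> screen -> map -> call -> tabulate -> logo.

``run_pipeline`` drives the whole chain from a :class:`RunConfig` and
writes a deterministic report bundle: per-library dinucleotide tables,
site lists (TSV + BED), non-TA consensus logos for each library and the
combined frame, side-bias and end-match summaries, and a machine-
readable ``summary.json`` with stage counts that must balance. Inputs
can be simulated (the default study conditions), or supplied as FASTQ
libraries plus a reference, or as pre-computed SAM alignments from an
external aligner.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from scipy.stats import beta as beta_dist

from . import logo as logomod
from . import mapping, screen, simulate, sites as sitesmod
from .constructs import ConstructRegistry, TransposonConstruct, default_registry
from .seqcore import ReferenceGenome, read_fasta
from .simulate import SimulationParams

__all__ = ["RunConfig", "run_pipeline", "render_report", "clopper_pearson"]


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run.

    ``mode`` selects the entry point: ``"simulate"`` generates genome
    and reads from ``sim``; ``"reads"`` uses ``reference`` +
    ``left_fastq``/``right_fastq``; ``"sam"`` uses ``reference`` +
    ``left_sam``/``right_sam``. Either library may be omitted in the
    reads/sam modes.
    """

    output_dir: str = "sbsites_run"
    mode: str = "simulate"
    seed: int = 0
    construct: str = "pYT11"
    registry_path: str | None = None
    reference: str | None = None
    left_fastq: str | None = None
    right_fastq: str | None = None
    left_sam: str | None = None
    right_sam: str | None = None
    # stage parameters
    max_end_mismatches: int = 1
    min_genomic_len: int = 20
    k: int = 12
    max_mismatches: int = 2
    min_fragment_len: int = 20
    mapq_min: int = 20
    W: int = 10
    pseudocount: float = 0.1
    motif_window: int = 4
    sim: SimulationParams | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "reads", "sam"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.sim is None:
            self.sim = SimulationParams(seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = SimulationParams(**sim)
        return cfg

    def resolve_construct(self) -> TransposonConstruct:
        reg = (
            ConstructRegistry.load(self.registry_path)
            if self.registry_path
            else default_registry()
        )
        return reg.get(self.construct)


def _logo_bundle(
    windows, pseudocount: float, motif: str, L: int, prefix: Path
) -> dict:
    """Write PFM TSV + text + SVG logos; return summary metrics."""
    pfm = logomod.build_pfm(windows, pseudocount)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    (prefix.with_suffix(".pfm.tsv")).write_text(logomod.render_pfm_tsv(pfm))
    (prefix.with_suffix(".logo.txt")).write_text(logomod.render_text_logo(pfm))
    (prefix.with_suffix(".svg")).write_text(logomod.render_svg_logo(pfm))
    return {
        "n_windows": pfm.n_sequences,
        "consensus": pfm.consensus(),
        "side_bias_bits": logomod.side_bias(pfm, L=L),
        "end_match_score": logomod.end_match_score(pfm, motif),
        "files": {
            "pfm": prefix.with_suffix(".pfm.tsv").name,
            "text_logo": prefix.with_suffix(".logo.txt").name,
            "svg": prefix.with_suffix(".svg").name,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain; returns (and writes) the run summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    construct = config.resolve_construct()
    summary: dict = {
        "construct": construct.name,
        "seed": config.seed,
        "mode": config.mode,
        "parameters": {
            "max_end_mismatches": config.max_end_mismatches,
            "min_genomic_len": config.min_genomic_len,
            "k": config.k,
            "max_mismatches": config.max_mismatches,
            "min_fragment_len": config.min_fragment_len,
            "mapq_min": config.mapq_min,
            "W": config.W,
            "pseudocount": config.pseudocount,
        },
        "stages": {},
        "libraries": {},
    }

    # ---- inputs -----------------------------------------------------
    truth_events = None
    if config.mode == "simulate":
        sim = config.sim
        dataset = simulate.simulate_dataset(sim, construct, out / "sim")
        genome = dataset.genome
        truth_events = dataset.events
        fastqs = {"left": dataset.left_fastq, "right": dataset.right_fastq}
        summary["stages"]["simulate"] = {
            "n_events": len(dataset.events),
            "n_reads_left": dataset.read_stats.n_reads_left,
            "n_reads_right": dataset.read_stats.n_reads_right,
            "skipped_events": dataset.read_stats.skipped_events,
        }
        summary["parameters"]["sim"] = dataclasses.asdict(sim)
    else:
        if not config.reference:
            raise ValueError(f"mode {config.mode!r} requires a reference FASTA")
        genome = read_fasta(config.reference)
        fastqs = {"left": config.left_fastq, "right": config.right_fastq}

    # ---- per-library screen/map/call --------------------------------
    index = None
    per_side_sites: dict[str, list] = {}
    per_side_windows: dict[str, dict[str, list]] = {}
    for side in ("left", "right"):
        lib: dict = {}
        if config.mode == "sam":
            sam_path = config.left_sam if side == "left" else config.right_sam
            if not sam_path:
                continue
            alignments = mapping.import_sam(
                sam_path, side, genome, config.mapq_min
            )
            lib["alignments"] = {"input": len(alignments)}
        else:
            fastq = fastqs.get(side)
            if not fastq:
                continue
            trimmed, sstats = screen.screen_and_trim(
                fastq, construct, side,
                config.max_end_mismatches, config.min_genomic_len,
            )
            assert sstats.balanced(), "screen stats do not balance"
            lib["screen"] = dataclasses.asdict(sstats)
            if index is None:
                index = mapping.build_index(genome, config.k)
            alignments = mapping.map_fragments(
                index, genome, trimmed, config.max_mismatches
            )
        kept, fstats = mapping.filter_alignments(
            alignments, config.min_fragment_len
        )
        assert fstats.balanced(), "filter stats do not balance"
        lib["filter"] = dataclasses.asdict(fstats)

        called, discarded = sitesmod.call_sites(kept, genome, side)
        unique, duplicates = sitesmod.dedupe_sites(called)
        assert len(called) == len(kept) - discarded
        assert len(unique) + duplicates == len(called)
        lib["sites"] = {
            "called": len(called),
            "discarded_out_of_bounds": discarded,
            "pcr_duplicates": duplicates,
            "unique": len(unique),
        }
        per_side_sites[side] = unique

        table = sitesmod.dinucleotide_table(unique, f"{construct.name}-{side}")
        pct = sitesmod.nonTA_proportion(table)
        lib["table"] = {
            "counts": table.counts,
            "total": table.total,
            "non_TA_total": table.nonTA_total,
            "non_TA_proportion_pct": None if math.isnan(pct) else round(pct, 3),
        }
        sitesmod.write_sites_tsv(unique, out / f"sites_{side}.tsv")
        sitesmod.write_sites_bed(unique, out / f"sites_{side}.bed")
        (out / f"table_{side}.tsv").write_text(sitesmod.format_table(table))
        non_ta = [s for s in unique if not s.is_TA]
        sitesmod.write_sites_tsv(non_ta, out / f"sites_{side}_nonTA.tsv")

        windows = {
            "TA": logomod.extract_flanks(
                genome, [s for s in unique if s.is_TA], config.W
            ),
            "nonTA": logomod.extract_flanks(genome, non_ta, config.W),
        }
        per_side_windows[side] = windows
        motif = construct.motif(side)
        for klass, wins in windows.items():
            if not wins:
                lib[f"logo_{klass}"] = {"n_windows": 0, "note": "skipped: no sites"}
                continue
            lib[f"logo_{klass}"] = _logo_bundle(
                wins, config.pseudocount, motif, config.motif_window,
                out / f"logo_{side}_{klass}",
            )
        summary["libraries"][side] = lib

    if not summary["libraries"]:
        raise ValueError("no input libraries were provided")

    # ---- combined non-TA frame --------------------------------------
    left_nt = per_side_windows.get("left", {}).get("nonTA", [])
    right_nt = per_side_windows.get("right", {}).get("nonTA", [])
    if left_nt or right_nt:
        combined = logomod.combine_sides(left_nt, right_nt, config.pseudocount)
        prefix = out / "logo_combined_nonTA"
        prefix.with_suffix(".pfm.tsv").write_text(logomod.render_pfm_tsv(combined))
        prefix.with_suffix(".logo.txt").write_text(
            logomod.render_text_logo(combined)
        )
        prefix.with_suffix(".svg").write_text(logomod.render_svg_logo(combined))
        summary["combined_nonTA_logo"] = {
            "n_windows": combined.n_sequences,
            "consensus": combined.consensus(),
            "consensus_distal_motif_window": combined.consensus()[
                config.W + 2 : config.W + 2 + config.motif_window
            ],
            "end_match_score": logomod.end_match_score(
                combined, construct.end_motif
            ),
        }
    else:
        summary["combined_nonTA_logo"] = {"n_windows": 0, "note": "skipped: no non-TA sites"}

    # ---- event-level non-TA rate ------------------------------------
    libs = summary["libraries"]
    if len(libs) == 2:
        tot = sum(libs[s]["table"]["total"] for s in libs)
        non_ta_total = sum(libs[s]["table"]["non_TA_total"] for s in libs)
        if tot:
            # each event contributes one site per library and an aberrant
            # event is non-TA in exactly one of them, so the event-level
            # rate is the pooled site-level proportion scaled by 2
            rate = 100.0 * non_ta_total / (tot / 2.0)
            lo, hi = clopper_pearson(non_ta_total, tot)
            summary["non_TA_event_rate"] = {
                "percent": round(rate, 4),
                "ci95_percent": [round(200 * lo, 4), round(200 * hi, 4)],
                "non_TA_sites": non_ta_total,
                "total_sites": tot,
            }

    # ---- truth comparison (simulation mode) -------------------------
    if truth_events is not None:
        truth_cmp = {}
        for side in ("left", "right"):
            called_set = {
                (s.chrom, s.dinuc_start, s.strand)
                for s in per_side_sites.get(side, [])
            }
            truth_set = simulate.truth_site_set(truth_events, side)
            truth_cmp[side] = {
                "truth_sites": len(truth_set),
                "called_sites": len(called_set),
                "missed": len(truth_set - called_set),
                "spurious": len(called_set - truth_set),
            }
        summary["truth_comparison"] = truth_cmp

    # ---- outputs ----------------------------------------------------
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "report.txt").write_text(render_report(summary))
    config.to_yaml(out / "config_used.yaml")
    return summary


def render_report(summary: dict) -> str:
    """Human-readable report: count tables in canonical row order,
    proportions at 3 decimals, logo files referenced by path."""
    lines = [
        f"sbsites run — construct {summary['construct']}, "
        f"mode {summary['mode']}, seed {summary['seed']}",
        "",
    ]
    for side, lib in summary["libraries"].items():
        t = lib["table"]
        lines.append(f"== {side} library ==")
        if "screen" in lib:
            s = lib["screen"]
            lines.append(
                f"reads: {s['total']} total, {s['matched']} end-matched, "
                f"{s['too_short']} too short, {s['rejected']} rejected"
            )
        f = lib["filter"]
        lines.append(
            f"alignments: {f['kept']} kept, {f['ambiguous']} ambiguous, "
            f"{f['unmapped']} unmapped, {f['too_short']} too short"
        )
        lines.append(
            f"unique sites: {lib['sites']['unique']} "
            f"({lib['sites']['pcr_duplicates']} duplicates removed)"
        )
        lines.append("dinucleotide\tcount")
        for d in sitesmod.DINUC_ORDER:
            lines.append(f"{d}\t{t['counts'][d]}")
        lines.append(f"total\t{t['total']}")
        pct = t["non_TA_proportion_pct"]
        lines.append(
            "non-TA proportion\t"
            + ("NA" if pct is None else f"{pct:.3f}%")
        )
        for klass in ("nonTA", "TA"):
            info = lib.get(f"logo_{klass}", {})
            if info.get("n_windows"):
                lines.append(
                    f"{klass} logo: n={info['n_windows']}, side_bias="
                    f"{info['side_bias_bits']:.3f} bits, end_match="
                    f"{info['end_match_score']:.2f} "
                    f"({info['files']['text_logo']})"
                )
            elif info:
                lines.append(f"{klass} logo: {info.get('note', 'skipped')}")
        lines.append("")
    comb = summary.get("combined_nonTA_logo", {})
    if comb.get("n_windows"):
        lines.append(
            f"combined non-TA logo: n={comb['n_windows']}, distal consensus "
            f"+1..+{len(comb['consensus_distal_motif_window'])} = "
            f"{comb['consensus_distal_motif_window']}, end_match="
            f"{comb['end_match_score']:.2f}"
        )
    elif comb:
        lines.append(f"combined non-TA logo: {comb.get('note', 'skipped')}")
    rate = summary.get("non_TA_event_rate")
    if rate:
        lines.append(
            f"event-level non-TA rate: {rate['percent']:.3f}% "
            f"(95% CI {rate['ci95_percent'][0]:.3f}–{rate['ci95_percent'][1]:.3f}%)"
        )
    return "\n".join(lines) + "\n"
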