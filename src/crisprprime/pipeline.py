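"""End-to-end pipeline: amplicons -> new spacers -> protospacers -> statistics."""

from __future__ import annotations

import copy
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrays import count_independent_events, parse_amplicons, summarize_array_activity
from .io import (
    dump_yaml,
    hits_to_frame,
    read_array_models,
    read_fasta,
    read_plasmid,
    read_primed_site_spec,
    write_bed,
    write_fasta,
    write_tsv,
)
from .mapping import PAM_CONSENSUS, length_distribution, map_spacer
from .simulate import PrimedSite
from .stats import (
    clustering_test,
    fit_processivity,
    flank_logo,
    flank_logos_by_length,
    scan_pams,
    signed_distance,
    strand_direction_summary,
    window_density,
)


class PipelineError(RuntimeError):
    """Structural failure the pipeline cannot continue past."""


@dataclass
class PipelineConfig:
    plasmid_fasta: str
    amplicons_fasta: str
    array_models: str
    primed_site: str
    out_dir: str
    max_mismatch: int = 0
    repeat_max_mismatch: int = 3
    window_frac: float = 0.05
    step_frac: float = 0.01
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def locate_primed_site(plasmid, spec: dict) -> PrimedSite:
    """Resolve a primed-site spec (spacer sequence + PAM variant) on the plasmid."""
    hits = map_spacer(spec["spacer"], plasmid, max_mismatch=0)
    hits = [h for h in hits if not h.ambiguous]
    if len(hits) != 1:
        raise PipelineError(
            f"priming spacer must map uniquely and exactly; found {len(hits)} placements"
        )
    hit = hits[0]
    hit.hit_id = "primed"
    return PrimedSite(
        protospacer=hit,
        pam_variant=spec["pam_variant"],
        priming_spacer_seq=hit.seq,
        plasmid_length=len(plasmid),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Parse -> identify -> map -> PAM/length -> distances -> windows -> logos.

    Per-record problems are accumulated in ``results["problems"]``; structural
    problems (missing/empty inputs) raise :class:`PipelineError`.
    """
    plasmid = read_plasmid(config.plasmid_fasta)
    models = read_array_models(config.array_models)
    site = locate_primed_site(plasmid, read_primed_site_spec(config.primed_site))
    amplicons = read_fasta(config.amplicons_fasta)
    if not amplicons:
        raise PipelineError(f"no amplicon records in {config.amplicons_fasta}")

    genotypes, problems = parse_amplicons(
        amplicons, models, max_mismatch=config.repeat_max_mismatch
    )
    if not genotypes:
        raise PipelineError("no genotype could be parsed from the amplicons")

    activity = summarize_array_activity(genotypes)
    independent = count_independent_events(genotypes)

    # map every new-spacer occurrence (duplicates across clones are distinct
    # acquisition events and all contribute to the distributions)
    hits = []
    unmapped = 0
    cache: dict[str, list] = {}
    for g in genotypes:
        for array_id, new in sorted(g.new_spacers.items()):
            for i, spacer in enumerate(new):
                placements = cache.get(spacer)
                if placements is None:
                    placements = map_spacer(spacer, plasmid, config.max_mismatch)
                    cache[spacer] = placements
                if not placements:
                    unmapped += 1
                    problems.append(
                        {"record": f"{g.pim_id}|{array_id}[{i}]", "error": "unmapped spacer"}
                    )
                    continue
                best = min(h.mismatches for h in placements)
                for h in placements:
                    if h.mismatches == best:
                        h2 = copy.copy(h)
                        h2.hit_id = f"{g.pim_id}|{array_id}[{i}]"
                        hits.append(h2)

    lengths = length_distribution(hits)
    pam_class_counts = (
        pd.Series([h.pam_class for h in hits]).value_counts().rename_axis("pam_class").to_frame("count")
        if hits
        else pd.DataFrame(columns=["count"])
    )

    pams = scan_pams(plasmid, "GG")
    L = len(plasmid)
    records = []
    for h in hits:
        if not h.ambiguous:
            records.append(signed_distance(h, site, L))
    summary = strand_direction_summary(records)
    windows = window_density(
        hits, pams, L, site=site, window_frac=config.window_frac, step_frac=config.step_frac
    )
    clustering = None
    if len(records) >= 5:
        stat, p = clustering_test(records, pams, site, n_perm=config.n_perm, seed=config.seed)
        clustering = {"mean_abs_distance_bp": stat, "p_value": p}

    consensus_hits = [h for h in hits if h.pam_class == PAM_CONSENSUS and not h.ambiguous]
    logos = {"all": flank_logo(hits)} if hits else {}
    logos.update(flank_logos_by_length(hits))

    # decay-scale fit from hits on the non-target strand 5' of the site:
    # under the translocation model these are dominated by the NTS leg
    nts5 = [abs(r.d) for r in records if r.ts_label == "NTS" and r.dir_label == "5prime"]
    processivity = fit_processivity(nts5, seed=config.seed) if len(nts5) >= 5 else None

    return {
        "plasmid": plasmid,
        "site": site,
        "genotypes": genotypes,
        "problems": problems,
        "activity": activity,
        "independent_events": independent,
        "hits": hits,
        "unmapped": unmapped,
        "lengths": lengths,
        "pam_class_counts": pam_class_counts,
        "pam_positions": pams,
        "distance_records": records,
        "strand_direction": summary,
        "windows": windows,
        "clustering": clustering,
        "logos": logos,
        "processivity": processivity,
        "config": config,
    }


def write_outputs(results: dict, out_dir=None) -> Path:
    """Write all pipeline tables; returns the output directory."""
    config: PipelineConfig = results["config"]
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = len(results["plasmid"])

    hits = results["hits"]
    write_tsv(hits_to_frame(hits), out / "protospacers.tsv")
    write_bed(hits, out / "protospacers.bed", L=L)
    write_fasta(
        [(h.hit_id or f"hit{i}", h.seq) for i, h in enumerate(hits)],
        out / "new_spacers.fasta",
    )
    write_tsv(results["lengths"], out / "length_distribution.tsv", index=True)
    write_tsv(results["pam_class_counts"], out / "pam_classes.tsv", index=True)

    rec_df = pd.DataFrame(
        [
            {"hit_id": r.hit_id, "d": r.d, "hit_strand": r.hit_strand,
             "ts_label": r.ts_label, "dir_label": r.dir_label}
            for r in results["distance_records"]
        ]
    )
    write_tsv(rec_df, out / "distances.tsv")
    write_tsv(results["windows"], out / "windows.tsv")
    write_tsv(results["strand_direction"]["counts"], out / "strand_direction_counts.tsv", index=True)
    write_tsv(results["strand_direction"]["percent"], out / "strand_direction_percent.tsv", index=True)

    act = results["activity"]
    write_tsv(act["per_array"], out / "activity_per_array.tsv", index=True)
    write_tsv(act["arrays_with_k"], out / "activity_arrays_with_k.tsv")
    write_tsv(act["pims_with_total"], out / "activity_pims_with_total.tsv")
    write_tsv(act["combinations"], out / "activity_combinations.tsv")

    for name, logo in results["logos"].items():
        df = logo.freq.copy()
        df["info_bits"] = logo.info_bits
        write_tsv(df, out / f"logo_{name}.tsv", index=True)

    scalars = {
        "n_genotypes": len(results["genotypes"]),
        "n_new_spacers": len(results["hits"]),
        "n_unmapped": results["unmapped"],
        "independent_events_lower_bound": results["independent_events"],
        "clustering": results["clustering"],
        "processivity_bp": (
            None if results["processivity"] is None else results["processivity"].mean_bp
        ),
        "seed": config.seed,
    }
    dump_yaml(scalars, out / "summary.yaml")

    if results["problems"]:
        write_tsv(pd.DataFrame(results["problems"]), out / "problems.tsv")

    log = [
        f"crisprprime {__version__}",
        f"python {sys.version.split()[0]}",
        f"plasmid {results['plasmid'].id} ({L} bp, circular)",
        f"config: {asdict(config)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
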