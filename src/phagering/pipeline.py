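"""End-to-end orchestration of the phage discovery workflow.

Stages run in dependency order on a synthetic community (or user-supplied
FASTA): simulate -> circularity screen -> gene calling -> marker
classification -> dereplication -> CRISPR host prediction -> DGR detection
-> read recruitment / abundance.  Each stage writes plain files (FASTA/TSV)
into the output directory and the run finishes with a JSON manifest holding
the config snapshot, seeds, per-stage output digests and timings, plus a
funnel summary (contigs surviving each filter).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import fractional_abundance, recruit_reads
from .circular import Contig, screen_contigs
from .derep import cluster_proteins, dereplicate_genomes
from .dgr import adenine_bias_test, find_repeat_pairs
from .genes import CODES, call_orfs
from .hosts import match_spacers, predict_hosts
from .markers import classify_contigs, load_packaged_profiles
from .synthetic import (
    CommunityConfig,
    DgrSpec,
    generate_community,
    generate_reads,
    write_fasta,
    write_fastq,
)


class DependencyError(RuntimeError):
    """A stage's required upstream output is missing."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def community_config_from_dict(d: dict) -> CommunityConfig:
    d = dict(d)
    if "dgr_specs" in d:
        d["dgr_specs"] = tuple(DgrSpec(**s) for s in d["dgr_specs"])
    for key in ("phage_length_range", "plasmid_length_range",
                "linear_length_range", "repeat_length_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "spacer_specs" in d:
        d["spacer_specs"] = {g: tuple(v) for g, v in d["spacer_specs"].items()}
    return CommunityConfig(**d)


def run_pipeline(config: dict | None = None, out_dir="pipeline_out", seed: int = 0):
    """Run the full workflow on a synthetic community; returns the manifest.

    ``config`` keys (all optional): ``community`` (CommunityConfig fields),
    ``e1``/``e2`` (round cutoffs), ``ani_min``/``cov_min``, ``n_reads``,
    ``read_length``.
    """
    config = config or {}
    e1 = float(config.get("e1", 0.05))
    e2 = float(config.get("e2", 0.01))
    if e2 > e1:
        raise ValueError("round-2 e-value cutoff must not be looser than round 1")
    all_stages = ("simulate", "screen", "markers", "derep", "hosts", "dgr",
                  "abundance")
    enabled = set(config.get("stages", all_stages))
    unknown = enabled - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for required in ("simulate", "screen", "markers"):
        if required not in enabled:
            raise DependencyError(f"stage '{required}' cannot be skipped")
    for dependent in ("hosts", "abundance"):
        if dependent in enabled and "derep" not in enabled:
            raise DependencyError(f"stage '{dependent}' requires stage 'derep'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }
    funnel: dict[str, int] = {}

    def stage(name):
        t0 = time.time()

        def done(*files):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3),
                "outputs": {f.name: _digest(f) for f in files},
            }

        return done

    # ---- simulate -----------------------------------------------------
    done = stage("simulate")
    comm_cfg = community_config_from_dict(
        {**config.get("community", {}), "seed": seed}
    )
    contigs, truth = generate_community(comm_cfg)
    fa = out / "contigs.fasta"
    write_fasta(contigs, fa)
    truth.to_dir(out)
    funnel["contigs"] = len(contigs)
    done(fa)

    # ---- circularity screen ------------------------------------------
    done = stage("screen")
    calls = screen_contigs([Contig(cid, s) for cid, s in contigs.items()])
    screen_df = pd.DataFrame(
        [
            {"contig_id": c.contig_id, "is_circular": c.is_circular,
             "repeat_length": c.repeat_length or 0, "reason": c.reason}
            for c in calls
        ]
    )
    screen_path = out / "circular_screen.tsv"
    screen_df.to_csv(screen_path, sep="\t", index=False)
    circular = {c.contig_id: c.canonical_seq for c in calls if c.is_circular}
    # the funnel continues with circular contigs only (likely closed genomes)
    working = dict(circular)
    circular_flags = {cid: True for cid in working}
    funnel["circular"] = len(circular)
    done(screen_path)

    # ---- marker classification (round 1 + recoding + round 2) --------
    done = stage("markers")
    profiles = list(load_packaged_profiles())
    phage_calls = classify_contigs(
        working, profiles, e1=e1, e2=e2, circular_flags=circular_flags
    )
    calls_df = pd.DataFrame(
        [
            {"contig_id": c.contig_id, "is_phage": c.is_phage,
             "markers": ",".join(sorted(c.markers_found)),
             "round1_pass": c.round1_pass, "round2_pass": c.round2_pass,
             "genetic_code": c.code_id, "length": c.length}
            for c in phage_calls
        ]
    )
    calls_path = out / "phage_calls.tsv"
    calls_df.to_csv(calls_path, sep="\t", index=False)
    funnel["round1_hit"] = int(calls_df.round1_pass.sum())
    funnel["phage"] = int(calls_df.is_phage.sum())
    phage_ids = sorted(calls_df.loc[calls_df.is_phage, "contig_id"])
    done(calls_path)

    # ---- dereplication -----------------------------------------------
    reps = {}
    if "derep" in enabled:
        done = stage("derep")
        if not phage_ids:
            raise DependencyError(
                "derep: no phage genomes from the markers stage"
            )
        phage_seqs = {cid: working[cid] for cid in phage_ids}
        gclusters = dereplicate_genomes(
            phage_seqs,
            ani_min=float(config.get("ani_min", 95.0)),
            cov_min=float(config.get("cov_min", 80.0)),
            circular=True,
        )
        derep_path = out / "genome_clusters.tsv"
        pd.DataFrame(
            [
                {"member": m, "representative": cl.representative}
                for cl in gclusters for m in cl.members
            ]
        ).to_csv(derep_path, sep="\t", index=False)
        reps = {cl.representative: phage_seqs[cl.representative] for cl in gclusters}
        funnel["representatives"] = len(reps)
        done(derep_path)

    # ---- CRISPR host prediction --------------------------------------
    if "hosts" in enabled:
        done = stage("hosts")
        matches = match_spacers(truth.spacers, reps, circular=True)
        preds, cross = predict_hosts(matches, truth.spacers)
        hosts_path = out / "host_predictions.tsv"
        pd.DataFrame(
            [
                {"contig_id": p.contig_id,
                 "genus": ",".join(sorted(p.taxa_by_rank.get("genus", set()))),
                 "multi_genus": p.multi_genus, "n_spacers": p.n_spacers}
                for p in preds
            ]
        ).to_csv(hosts_path, sep="\t", index=False)
        funnel["crispr_targeted"] = len(preds)
        done(hosts_path)

    # ---- DGR detection ------------------------------------------------
    dgr_rows = []
    if "dgr" in enabled:
        done = stage("dgr")
        _find_dgrs(truth, contigs, dgr_rows)
        dgr_path = out / "dgr_report.tsv"
        pd.DataFrame(
            dgr_rows,
            columns=["contig_id", "tr_start", "tr_end", "vr_start", "vr_end",
                     "identity", "within_window", "n_a_substituted",
                     "n_nona_substituted", "p_value", "hypervariable"],
        ).to_csv(dgr_path, sep="\t", index=False)
        funnel["dgr_pairs"] = len(dgr_rows)
        done(dgr_path)

    # ---- abundance ----------------------------------------------------
    if "abundance" in enabled:
        done = stage("abundance")
        n_reads = int(config.get("n_reads", 20_000))
        read_length = int(config.get("read_length", 100))
        phage_truth_seqs = {cid: contigs[cid] for cid in truth.abundance}
        reads = generate_reads(
            phage_truth_seqs, truth.abundance, n_reads, read_length,
            seed=seed + 1, circular=True,
        )
        fq = out / "reads.fastq"
        write_fastq(reads, fq)
        rec = recruit_reads(reads, reps, circular=True)
        table = fractional_abundance(
            rec.counts, {g: len(s) for g, s in reps.items()}
        )
        ab_path = out / "abundance.tsv"
        table.to_csv(ab_path, sep="\t", index=False)
        funnel["detected_genomes"] = int(table.detected.sum())
        done(fq, ab_path)

    # ---- summary ------------------------------------------------------
    manifest["funnel"] = funnel
    summary_path = out / "summary.tsv"
    pd.Series(funnel, name="count").rename_axis("stage").to_csv(
        summary_path, sep="\t"
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _find_dgrs(truth, contigs, dgr_rows):
    for _, row in truth.dgrs.drop_duplicates("contig_id").iterrows():
        cid = row.contig_id
        seq = contigs[cid]  # coordinates in truth refer to the raw contig
        pairs = find_repeat_pairs(
            seq, (int(row.rt_start), int(row.rt_end)), genome_id=cid
        )
        for p in pairs:
            tr = seq[p.tr_start : p.tr_end]
            vr = seq[p.vr_start : p.vr_end]
            rep = adenine_bias_test(tr, [vr], genome_id=cid)
            dgr_rows.append(
                {"contig_id": cid, "tr_start": p.tr_start, "tr_end": p.tr_end,
                 "vr_start": p.vr_start, "vr_end": p.vr_end,
                 "identity": round(p.identity, 2),
                 "within_window": p.within_10kb_window,
                 "n_a_substituted": rep.n_a_substituted,
                 "n_nona_substituted": rep.n_nona_substituted,
                 "p_value": rep.p_value, "hypervariable": rep.hypervariable}
            )
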