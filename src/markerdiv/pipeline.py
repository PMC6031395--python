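"""End-to-end orchestration: simulate -> screen -> place -> diversity -> selection.

Each stage is a thin wrapper over the library modules; ``run_pipeline`` chains
them, writes TSV/FASTA/Newick outputs plus a JSON manifest, and is fully
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, io, phylo, profile_hmm, selection, synthetic
from ._model import GAP

__all__ = [
    "RunManifest",
    "build_group_profiles",
    "screen_and_align",
    "place_fragments",
    "run_pipeline",
]

logger = logging.getLogger("markerdiv")

VERSION = "0.1.0"


@dataclass
class RunManifest:
    version: str
    config_hash: str
    n_fragments: int
    n_hits: int
    n_placed: int
    per_group_placed: dict[str, int]
    outputs: dict[str, str]
    timings: dict[str, float]

    def validate(self) -> None:
        if not (self.n_placed <= self.n_hits <= self.n_fragments):
            raise ValueError("manifest counts must satisfy placed <= hits <= fragments")


def community_from_config(cfg: io.RunConfig) -> synthetic.SimulatedCommunity:
    return synthetic.make_community(
        synthetic.CommunityConfig(
            groups=tuple(synthetic.GroupSpec(*g) for g in cfg.groups),
            fragment_count=cfg.fragment_count,
            fragment_min_len=cfg.fragment_min_len,
            fragment_max_len=cfg.fragment_max_len,
            alignment_len=cfg.alignment_len,
            stem_depth=cfg.stem_depth,
            seed=cfg.seed,
        )
    )


def build_group_profiles(
    community: synthetic.SimulatedCommunity,
    n_null: int = 300,
    match_gap_frac: float = 0.5,
    seed: int = 0,
) -> dict[str, profile_hmm.Profile]:
    """One calibrated profile per taxonomic group of the community."""
    profiles = {}
    groups = sorted({g for g in community.reference_groups.values()})
    for gi, group in enumerate(groups):
        aln = community.group_alignment(group)
        prof = profile_hmm.build_profile(
            profile_hmm.trim_gap_columns(aln),
            source_group=group,
            match_gap_frac=match_gap_frac,
        )
        profiles[group] = profile_hmm.calibrate(
            prof, n_null=n_null, seed=seed + 1009 * (gi + 1)
        )
    return profiles


def screen_and_align(
    profiles: dict[str, profile_hmm.Profile],
    fragments: list[synthetic.Fragment],
    evalue_max: float = 1e-5,
    min_len: int = 150,
) -> tuple[list[profile_hmm.SearchHit], list[profile_hmm.AlignedFragment]]:
    """Screen fragments at the E-value/length gate, align accepted ones."""
    plist = [profiles[g] for g in sorted(profiles)]
    hits = profile_hmm.search(
        plist, [(f.id, f.seq) for f in fragments],
        evalue_max=evalue_max, min_len=min_len,
    )
    seqs = {f.id: f.seq for f in fragments}
    aligned = [
        profile_hmm.align_to_profile(profiles[h.best_profile], h.fragment_id, seqs[h.fragment_id])
        for h in hits
    ]
    return hits, aligned


def place_fragments(
    community: synthetic.SimulatedCommunity,
    aligned: list[profile_hmm.AlignedFragment],
) -> tuple[phylo.ReferenceTree, list[phylo.Placement]]:
    """Place aligned fragments on the community's true reference tree."""
    ref = phylo.ReferenceTree(community.reference_tree, community.reference_groups)
    placements = []
    for frag in aligned:
        try:
            placements.append(phylo.place_query(ref, community.reference_seqs, frag))
        except phylo.UnplaceableError:
            logger.warning("fragment %s unplaceable; dropped", frag.fragment_id)
    return ref, placements


def _padded_rows(
    aligned: list[profile_hmm.AlignedFragment], n_cols: int
) -> dict[str, str]:
    rows = {}
    for frag in aligned:
        row = [GAP] * n_cols
        for col, res in zip(frag.column_map, frag.residues):
            if col is not None:
                row[col] = res
        rows[frag.fragment_id] = "".join(row)
    return rows


def run_pipeline(cfg: io.RunConfig, outdir: str | Path) -> RunManifest:
    """Run the full synthetic-community analysis and write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = str(path)

    t0 = time.perf_counter()
    community = community_from_config(cfg)
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d references, %d fragments",
                len(community.reference_ids), len(community.fragments))

    _save("references.fasta", lambda p: io.write_fasta(community.reference_seqs, p))
    _save("reference_tree.nwk", lambda p: io.write_newick(community.reference_tree, p))
    _save("fragments.fasta",
          lambda p: io.write_fasta({f.id: f.seq for f in community.fragments}, p))
    truth_df = pd.DataFrame(
        [
            (fid, t.group, t.lineage, t.start_col, t.length, t.paralog or "")
            for fid, t in sorted(community.truth.items())
        ],
        columns=["fragment_id", "group", "lineage", "start_col", "length", "paralog"],
    )
    _save("truth.tsv", lambda p: truth_df.to_csv(p, sep="\t", index=False))

    t0 = time.perf_counter()
    profiles = build_group_profiles(
        community, n_null=cfg.n_null, match_gap_frac=cfg.match_gap_frac,
        seed=cfg.seed + 77,
    )
    hits, aligned = screen_and_align(
        profiles, community.fragments, evalue_max=cfg.evalue_max, min_len=cfg.min_len
    )
    timings["screen"] = time.perf_counter() - t0
    logger.info("screen: %d/%d fragments hit at E<%g",
                len(hits), len(community.fragments), cfg.evalue_max)
    hits_df = pd.DataFrame(
        [(h.fragment_id, h.best_profile, h.bit_score, h.evalue, h.aligned_length)
         for h in hits],
        columns=["fragment_id", "group", "bit_score", "evalue", "aligned_length"],
    )
    _save("hits.tsv", lambda p: hits_df.to_csv(p, sep="\t", index=False))
    _save("aligned_fragments.fasta",
          lambda p: io.write_fasta(_padded_rows(aligned, cfg.alignment_len), p))
    colmap_rows = []
    for frag in aligned:
        for i, col in enumerate(frag.column_map):
            if col is not None:
                colmap_rows.append((frag.fragment_id, i, col))
    colmap_df = pd.DataFrame(
        colmap_rows, columns=["fragment_id", "residue_index", "column"]
    )
    _save("column_maps.tsv", lambda p: colmap_df.to_csv(p, sep="\t", index=False))

    t0 = time.perf_counter()
    ref, placements = place_fragments(community, aligned)
    timings["place"] = time.perf_counter() - t0
    logger.info("place: %d fragments placed", len(placements))
    plc_df = pd.DataFrame(
        [(p.fragment_id, p.edge, p.pendant_length, p.log_likelihood, p.assigned_group)
         for p in placements],
        columns=["fragment_id", "edge_id", "pendant_length", "log_likelihood", "group"],
    )
    _save("placements.tsv", lambda p: plc_df.to_csv(p, sep="\t", index=False))

    aligned_by_id = {a.fragment_id: a for a in aligned}
    by_group: dict[str, list[profile_hmm.AlignedFragment]] = {}
    for p in placements:
        if p.assigned_group != phylo.UNCLASSIFIED:
            by_group.setdefault(p.assigned_group, []).append(aligned_by_id[p.fragment_id])

    t0 = time.perf_counter()
    rich = diversity.richness_profile(
        by_group, n_cols=cfg.alignment_len, cutoffs=tuple(cfg.cutoffs),
        width=cfg.window_width, step=cfg.window_step, resample_n=cfg.resample_n,
        n_replicates=cfg.n_replicates, max_gap_frac=cfg.max_gap_frac,
        seed=cfg.seed + 31,
    )
    pdprof = diversity.pd_profile(
        by_group, n_cols=cfg.alignment_len, width=cfg.window_width,
        step=cfg.window_step, n_subsample=cfg.pd_subsample,
        max_gap_frac=cfg.max_gap_frac, seed=cfg.seed + 47,
    )
    timings["diversity"] = time.perf_counter() - t0
    _save("richness.tsv", lambda p: rich.to_csv(p, sep="\t", index=False))
    _save("pd.tsv", lambda p: pdprof.to_csv(p, sep="\t", index=False))

    # per-window log-rank between the first group and each other group
    groups = sorted(by_group)
    lr_rows = []
    if len(groups) >= 2 and len(cfg.cutoffs) >= 2:
        cutoff = cfg.cutoffs[1]
        for start in range(0, cfg.alignment_len - cfg.window_width + 1, cfg.window_step):
            slices = {
                g: diversity.slice_window(
                    by_group[g], start, width=cfg.window_width,
                    max_gap_frac=cfg.max_gap_frac, group=g,
                )
                for g in groups
            }
            for g in groups[1:]:
                a, b = slices[groups[0]], slices[g]
                if not a.members or not b.members:
                    continue
                res = diversity.compare_richness_logrank(
                    diversity.cluster_otus(a, cutoff),
                    diversity.cluster_otus(b, cutoff),
                )
                lr_rows.append((start, groups[0], g, cutoff, res.statistic, res.p_value))
    lr_df = pd.DataFrame(
        lr_rows,
        columns=["window_start", "group_a", "group_b", "cutoff", "statistic", "p_value"],
    )
    _save("logrank.tsv", lambda p: lr_df.to_csv(p, sep="\t", index=False))

    if cfg.codon_groups:
        kk_rows = []
        omegas: dict[str, list[float]] = {}
        for gi, (gname, omega, n_pairs) in enumerate(cfg.codon_groups):
            for k in range(int(n_pairs)):
                s1, s2 = synthetic.simulate_codon_pair(
                    synthetic.CodonPairSpec(
                        n_codons=cfg.codon_n, omega=float(omega), t=cfg.codon_t,
                        kappa=cfg.codon_kappa,
                        seed=cfg.seed + 7919 * (gi + 1) + k,
                    )
                )
                est = selection.kaks(s1, s2, pair_id=f"{gname}_{k}",
                                     seed=cfg.seed + 104729 + k)
                passed = selection.PairFilter().passes(est)
                kk_rows.append((est.pair_id, gname, est.ka, est.ks,
                                est.omega, est.se_pct, passed))
                if est.omega is not None:
                    omegas.setdefault(str(gname), []).append(est.omega)
        kk_df = pd.DataFrame(
            kk_rows,
            columns=["pair_id", "group", "ka", "ks", "omega", "se_pct", "passed_filter"],
        )
        _save("kaks.tsv", lambda p: kk_df.to_csv(p, sep="\t", index=False))
        gnames = [str(g[0]) for g in cfg.codon_groups]
        if len(gnames) >= 2 and all(omegas.get(g) for g in gnames[:2]):
            u, pval = selection.mann_whitney(omegas[gnames[0]], omegas[gnames[1]])
            payload = {
                "groups": gnames[:2],
                "U": u,
                "p_value": pval,
                "medians": {g: float(np.median(omegas[g])) for g in gnames[:2]},
            }
            _save("omega_test.json",
                  lambda p: p.write_text(json.dumps(payload, indent=2)))

    cfg_yaml = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    manifest = RunManifest(
        version=VERSION,
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
        n_fragments=len(community.fragments),
        n_hits=len(hits),
        n_placed=len(placements),
        per_group_placed={
            g: int(sum(1 for p in placements if p.assigned_group == g))
            for g in sorted({p.assigned_group for p in placements})
        },
        outputs=outputs,
        timings={k: round(v, 3) for k, v in timings.items()},
    )
    manifest.validate()
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    cfg.to_yaml(outdir / "config.yaml")
    return manifest
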