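"""Pipeline orchestration and the per-family database emission.

`run_pipeline` chains the stages discovery -> clustering -> alignment /
consensus -> signatures -> homology -> classification -> population
statistics -> relaxed linkage -> report, logging input/output counts per
stage and caching intermediates in the output directory so a run can be
resumed.  `emit_database` writes the master TSV (column groups ordered
classification -> structural -> homology -> linkage) plus one artifact
directory per cluster, and optionally a static HTML index; given the same
inputs the whole database is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, discovery, homology, msa, popgen, signatures
from .classify import (ClusterFeatures, TEClassification, assign_element_type,
                       classify_cluster, detect_solo_ltr, parse_entry_metadata)
from .homology import ReferenceLibrary, best_hit_summary, search_library, \
    write_hit_table
from .seqio import (MultipleAlignment, SequenceRecord, logger, read_fasta,
                    write_alignment, write_bed, write_fasta)
from .synthetic import packaged_fasta

DEFAULT_CONFIG: dict = {
    "genome": None,              # path to the assembly FASTA
    "min_identity": 0.94,        # self-alignment identity floor
    "min_hit_len": 400,          # minimum repeat copy length (nt)
    "min_copies": 3,             # minimum family size
    "cov_frac": 0.90,            # pile linkage coverage
    "cluster_id_min": 0.90,      # clustering identity (> rule)
    "cluster_cov_min": 0.90,     # clustering coverage of the shorter
    "e_max": 1e-15,              # homology positivity threshold
    "term_frac": 0.10,           # TIR terminal window fraction
    "ir_min_arm": 10,
    "ir_min_identity": 0.80,
    "ltr_min_len": 80,
    "ltr_min_identity": 0.85,
    "orf_min_nt": 300,
    "element_full_min": 0.90,    # element-type bands
    "element_remnant_max": 0.10,
    "relaxed_thresholds": [0.35, 0.50, 0.75, 0.90],
    "relaxed_cov_min": 0.50,
    "libraries": [],             # [{name, path, molecule, role}]
    "trna_library": "bundled",   # bundled | path | null
    "html_index": False,
}


def benchmark_config(genome_path: str | Path) -> dict:
    """Default config wired to the bundled synthetic domain libraries, as
    used for the desk-scale planted-family benchmark."""
    from .synthetic import bundled_library_specs
    cfg = dict(DEFAULT_CONFIG)
    cfg["genome"] = str(genome_path)
    cfg["libraries"] = bundled_library_specs()
    return cfg


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def setup_logging(outdir: Path | None = None,
                  level: str = "INFO") -> None:
    logger.setLevel(level.upper())
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, (logging.StreamHandler,
                                             logging.FileHandler))]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class ClusterDossier:
    cluster_id: int
    member_ids: list[str]
    alignment: MultipleAlignment | None
    consensus: msa.ConsensusSequence | None
    centroid_id: str | None
    centroid: SequenceRecord | None
    consensus_vs_centroid: dict = field(default_factory=dict)
    length_stats: msa.LengthStats | None = None
    truncation: msa.TruncationProfile | None = None
    inverted_repeats: list = field(default_factory=list)
    ltr_pairs: list = field(default_factory=list)
    ltr_identity_members: list[float] = field(default_factory=list)
    orfs: list = field(default_factory=list)
    ppt: object = None
    pbs: list = field(default_factory=list)
    hits_per_library: dict[str, list] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    classification: TEClassification | None = None
    p_dist: popgen.PairwiseDistanceSummary | None = None
    dnds: popgen.DnDsResult | None = None
    tajima: popgen.TajimaResult | None = None
    links: dict[float, list[int]] = field(default_factory=dict)


def _load_libraries(cfg: dict) -> list[ReferenceLibrary]:
    libs = []
    for spec in cfg["libraries"]:
        libs.append(ReferenceLibrary.from_fasta(
            spec["name"], spec["path"], spec["molecule"],
            spec.get("role", "")))
    return libs


def _trna_library(cfg: dict) -> list[SequenceRecord] | None:
    t = cfg.get("trna_library")
    if t == "bundled":
        return packaged_fasta("trna3_synthetic.fa")
    if t:
        return read_fasta(t)
    return None


def characterize_cluster(cid: int, members: list[SequenceRecord],
                         cfg: dict) -> ClusterDossier:
    """Alignment, consensus/centroid, structural signatures and length
    bookkeeping for one cluster."""
    aln = msa.progressive_align(members, source_cluster=cid)
    aln = msa.trim_sparse_ends(aln)
    cons = msa.build_consensus(aln, cluster_id=cid)
    cent_id = msa.select_centroid(members)
    cent = next(m for m in members if m.id == cent_id)
    dossier = ClusterDossier(
        cid, [m.id for m in members], aln, cons, cent_id, cent,
        consensus_vs_centroid=msa.compare_consensus_centroid(cons, cent),
        length_stats=msa.length_stats(members, cons),
        truncation=msa.truncation_profile(aln))
    cseq = cons.residues.upper()
    dossier.inverted_repeats = signatures.detect_inverted_repeats(
        cseq, min_arm=cfg["ir_min_arm"],
        min_arm_identity=cfg["ir_min_identity"])
    for ir in dossier.inverted_repeats:
        ir.geometry = signatures.classify_geometry(ir, len(cseq),
                                                   cfg["term_frac"])
    dossier.ltr_pairs = signatures.detect_direct_repeats(
        cseq, min_len=cfg["ltr_min_len"],
        min_identity=cfg["ltr_min_identity"])
    dossier.orfs = signatures.find_orfs(cseq, min_len_nt=cfg["orf_min_nt"])
    if dossier.ltr_pairs:
        pair = dossier.ltr_pairs[0]
        dossier.ppt = signatures.detect_ppt(cseq, pair)
        dossier.pbs = signatures.detect_pbs(cseq, pair, _trna_library(cfg))
        for m in members:  # within-element LTR identity, per member
            mp = signatures.detect_direct_repeats(
                m.residues, min_len=cfg["ltr_min_len"],
                min_identity=cfg["ltr_min_identity"])
            if mp:
                dossier.ltr_identity_members.append(
                    signatures.ltr_pair_identity(m.residues, mp[0]))
    return dossier


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 resume: bool = False) -> tuple[list[ClusterDossier], dict]:
    """Run the whole characterization pipeline; returns dossiers + summary."""
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = outdir / "cache"
    cache.mkdir(exist_ok=True)
    if not cfg.get("genome"):
        raise ValueError("config lacks a genome path")
    genome_path = Path(cfg["genome"])
    if not genome_path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    genome = read_fasta(genome_path)
    logger.info("stage genome: %d scaffold(s), %d nt",
                len(genome), sum(len(r) for r in genome))

    # --- discovery (cached) ---
    hits_path = cache / "hits.tsv"
    if resume and hits_path.exists():
        hits = discovery.read_hit_dump(hits_path)
        logger.info("stage discovery: reused %d cached hits", len(hits))
    else:
        hits = discovery.self_align_genome(
            genome, min_identity=cfg["min_identity"],
            min_hit_len=cfg["min_hit_len"])
        discovery.write_hit_dump(hits, hits_path)
    piles = discovery.build_piles(hits)
    families = discovery.call_families(
        piles, hits, genome, min_members=cfg["min_copies"],
        min_len=cfg["min_hit_len"], cov_frac=cfg["cov_frac"])
    write_bed([(fp, f"fam{f.id}") for f in families
               for fp in f.member_footprints()], outdir / "families.bed")
    members_all = [m for f in families for m in f.member_sequences]
    if members_all:
        write_fasta(members_all, outdir / "members.fasta")
    logger.info("stage discovery: %d hits, %d piles, %d families, %d copies",
                len(hits), len(piles), len(families), len(members_all))

    # --- clustering ---
    clusters, unclustered = clustering.cluster_sequences(
        members_all, id_min=cfg["cluster_id_min"],
        cov_min=cfg["cluster_cov_min"], min_members=cfg["min_copies"])
    clustering.write_membership(clusters, unclustered,
                                outdir / "clusters.tsv")
    logger.info("stage clustering: %d clusters, %d unclustered",
                len(clusters), len(unclustered))

    by_id = {m.id: m for m in members_all}
    libs = _load_libraries(cfg)
    lib_meta = {l.name: parse_entry_metadata(l) for l in libs}

    dossiers: list[ClusterDossier] = []
    for cl in clusters:
        members = [by_id[i] for i in cl.member_ids]
        d = characterize_cluster(cl.id, members, cfg)
        # homology
        query = d.consensus.record(prefix=f"cluster{cl.id}")
        for lib in libs:
            mode = ("translated_x_protein" if lib.molecule == "protein"
                    else "nucleotide")
            hits_l = search_library(query, lib, mode=mode,
                                    e_max=cfg["e_max"])
            if lib.molecule == "nucleotide" and lib.role == "known_te":
                # translated pass catches deteriorated elements
                hits_t = search_library(query, lib,
                                        mode="translated_x_translated",
                                        e_max=cfg["e_max"])
                seen = {h.subject_id for h in hits_l if h.positive}
                hits_l += [h for h in hits_t if h.subject_id not in seen]
            d.hits_per_library[lib.name] = hits_l
            d.summaries[lib.name] = best_hit_summary(hits_l, len(query.residues))
        # classification
        feats = ClusterFeatures(
            cl.id, query.residues, d.inverted_repeats, d.ltr_pairs, d.orfs,
            d.ppt, d.pbs, d.summaries,
            {l.name: l.role for l in libs}, lib_meta)
        d.classification = classify_cluster(feats)
        canonical = None
        for lib in libs:
            s = d.summaries.get(lib.name, {})
            if lib.role == "known_te" and s.get("positive"):
                canonical = next(e for e in lib.entries
                                 if e.id == s["best_match"])
                break
        assign_element_type(query.residues, canonical, d.classification,
                            cfg["element_full_min"], cfg["element_remnant_max"])
        # population statistics
        d.p_dist = popgen.p_distance(d.alignment)
        if len(members) >= 4:
            d.tajima = popgen.tajima_d(d.alignment)
        orfs_fwd = [o for o in d.orfs]
        if orfs_fwd:
            codon_rows = popgen.codon_alignment_from_orf(
                d.alignment, d.consensus, orfs_fwd[0])
            if len(codon_rows) >= 2 and len(next(iter(codon_rows.values()))) >= 3:
                d.dnds = popgen.nei_gojobori(codon_rows)
        dossiers.append(d)

    # solo-LTR re-labelling: lone arms matching some LTR cluster's LTR
    ltr_arms = []
    for d in dossiers:
        if d.classification.order == "LTR" and d.ltr_pairs:
            p = d.ltr_pairs[0]
            arm = d.consensus.residues.upper()[p.five_prime[0]:p.five_prime[1]]
            ltr_arms.append((f"cluster{d.cluster_id}", arm))
    for d in dossiers:
        if (d.classification.element_type in {"repeat-no-signature", "fragment"}
                and d.classification.order != "LTR" and ltr_arms
                and detect_solo_ltr(d.consensus.residues.upper(), ltr_arms)):
            d.classification.te_class = "I"
            d.classification.order = "LTR"
            d.classification.element_type = "Solo-LTR"
            d.classification.add("solo LTR", "matches an LTR family's arm "
                                 "at >=0.80 identity over >=0.80 of the arm")
    logger.info("stage classification: %d dossiers", len(dossiers))

    # relaxed linkage between cluster consensi
    consensi = {d.cluster_id: d.consensus.record() for d in dossiers}
    links = clustering.relaxed_link_pass(
        clusters, consensi, thresholds=cfg["relaxed_thresholds"],
        cov_min=cfg["relaxed_cov_min"])
    clustering.write_linkage(links, outdir / "linkage.tsv")
    for cl in clusters:
        for d in dossiers:
            if d.cluster_id == cl.id:
                d.links = cl.linked_cluster_ids
    logger.info("stage relaxed pass: %d links", len(links))

    emit_database(dossiers, outdir, html=cfg.get("html_index", False))
    summary = {
        "hits": len(hits), "piles": len(piles), "families": len(families),
        "copies": len(members_all), "clusters": len(clusters),
        "unclustered": len(unclustered), "links": len(links),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return dossiers, summary


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def dossier_row(d: ClusterDossier) -> dict:
    """One master-table row; column groups ordered classification ->
    structural -> homology -> linkage."""
    c = d.classification or TEClassification()
    row = {
        # classification (blue)
        "cluster_id": d.cluster_id,
        "te_class": c.te_class, "subclass": c.subclass, "order": c.order,
        "superfamily": c.superfamily, "family": c.family,
        "element_type": c.element_type,
        "evidence": json.dumps(c.evidence),
        "flag_identical_ltrs": c.activity_flags.get(
            "identical_within_element_ltrs", False),
        "flag_full_orf_domains": c.activity_flags.get(
            "full_orf_with_domains", False),
        "flag_expression": c.activity_flags.get("expression_hit", False),
        # structural (green)
        "n_members": len(d.member_ids),
        "longest_nt": d.length_stats.longest if d.length_stats else None,
        "shortest_nt": d.length_stats.shortest if d.length_stats else None,
        "consensus_nt": d.length_stats.consensus_len if d.length_stats else None,
        "longest_shortest_ratio": (d.length_stats.ratio
                                   if d.length_stats else None),
        "centroid": d.centroid_id,
        "consensus_centroid_identity": d.consensus_vs_centroid.get("identity"),
        "consensus_centroid_ratio": d.consensus_vs_centroid.get("length_ratio"),
        "largest_orf_nt": d.orfs[0].length_nt if d.orfs else 0,
        "largest_orf_frame": d.orfs[0].frame if d.orfs else None,
        "largest_orf_aa": d.orfs[0].aa_seq if d.orfs else "",
        "n_terminal_irs": sum(1 for i in d.inverted_repeats
                              if i.geometry == "terminal"),
        "n_subterminal_irs": sum(1 for i in d.inverted_repeats
                                 if i.geometry == "subterminal"),
        "n_palindromic_irs": sum(1 for i in d.inverted_repeats
                                 if i.geometry == "palindromic"),
        "has_ltr_pair": bool(d.ltr_pairs),
        "ltr_pair_identity_pct": (d.ltr_pairs[0].pair_identity
                                  if d.ltr_pairs else None),
        "member_ltr_identity_mean": (
            sum(d.ltr_identity_members) / len(d.ltr_identity_members)
            if d.ltr_identity_members else None),
        "ppt": bool(d.ppt),
        "pbs_trnas": ",".join(p.trna_id for p in d.pbs),
        "mean_p": d.p_dist.mean_p if d.p_dist else None,
        "sd_p": d.p_dist.sd_p if d.p_dist else None,
        "dN": d.dnds.dN if d.dnds else None,
        "dS": d.dnds.dS if d.dnds else None,
        "dN_dS": d.dnds.ratio if d.dnds else None,
        "tajima_S": d.tajima.S if d.tajima else None,
        "tajima_pi": d.tajima.pi if d.tajima else None,
        "tajima_D": d.tajima.D if d.tajima else None,
        "tajima_significant": d.tajima.significant if d.tajima else None,
    }
    # homology (orange)
    for lib in sorted(d.summaries):
        for f in homology.SUMMARY_FIELDS + ("positive",):
            row[f"{lib}.{f}"] = d.summaries[lib].get(f, "")
    # linkage (yellow)
    for t in sorted(d.links):
        row[f"linked_at_{int(t * 100)}"] = ",".join(
            str(x) for x in sorted(d.links[t]))
    return row


def emit_database(dossiers: list[ClusterDossier], outdir: str | Path,
                  html: bool = False) -> Path:
    """Master TSV plus one artifact directory per cluster."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [dossier_row(d) for d in
            sorted(dossiers, key=lambda x: x.cluster_id)]
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    df = pd.DataFrame([{c: _fmt(r.get(c)) for c in cols} for r in rows],
                      columns=cols if rows else list(_EMPTY_COLUMNS))
    master = outdir / "master.tsv"
    df.to_csv(master, sep="\t", index=False)

    for d in sorted(dossiers, key=lambda x: x.cluster_id):
        cdir = outdir / f"cluster_{d.cluster_id}"
        cdir.mkdir(exist_ok=True)
        if d.consensus is not None:
            with open(cdir / "consensus.fasta", "w") as fh:  # case-preserving
                fh.write(f">consensus_{d.cluster_id}\n{d.consensus.residues}\n")
        if d.centroid is not None:
            write_fasta([d.centroid], cdir / "centroid.fasta")
        if d.alignment is not None:
            write_alignment(d.alignment, cdir / "alignment.afa")
        if d.consensus is not None:
            with open(cdir / "irs.aln", "w") as fh:
                fh.write(signatures.ir_alignment_text(
                    d.consensus.residues.upper(), d.inverted_repeats))
        if d.truncation is not None:
            with open(cdir / "truncation.txt", "w") as fh:
                fh.write(d.truncation.rendering)
        hdir = cdir / "hits"
        hdir.mkdir(exist_ok=True)
        for lib, hits in sorted(d.hits_per_library.items()):
            write_hit_table(hits, hdir / f"{lib}.tsv")
        stats_rows = {k: _fmt(v) for k, v in dossier_row(d).items()
                      if not isinstance(v, str) or len(v) < 200}
        with open(cdir / "stats.tsv", "w") as fh:
            for k, v in stats_rows.items():
                fh.write(f"{k}\t{v}\n")
    if html:
        _write_html_index(dossiers, outdir)
    logger.info("stage report: %d master rows -> %s", len(rows), master)
    return master


_EMPTY_COLUMNS = ("cluster_id", "te_class", "subclass", "order",
                  "superfamily", "family", "element_type")


def _write_html_index(dossiers: list[ClusterDossier], outdir: Path) -> None:
    items = []
    for d in sorted(dossiers, key=lambda x: x.cluster_id):
        c = d.classification or TEClassification()
        items.append(
            f'<tr><td><a href="cluster_{d.cluster_id}/stats.tsv">'
            f"cluster {d.cluster_id}</a></td>"
            f"<td>{c.te_class}</td><td>{c.order}</td>"
            f"<td>{c.element_type}</td>"
            f'<td><a href="cluster_{d.cluster_id}/alignment.afa">aln</a> '
            f'<a href="cluster_{d.cluster_id}/consensus.fasta">consensus</a> '
            f'<a href="cluster_{d.cluster_id}/irs.aln">IRs</a></td></tr>')
    html = ("<html><body><h1>Repeat family database</h1>\n"
            '<p><a href="master.tsv">master table</a></p>\n'
            "<table border=1><tr><th>cluster</th><th>class</th><th>order</th>"
            "<th>element type</th><th>artifacts</th></tr>\n"
            + "\n".join(items) + "\n</table></body></html>\n")
    (outdir / "index.html").write_text(html)
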