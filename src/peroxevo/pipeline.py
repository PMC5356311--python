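"""End-to-end orchestration: inputs → model → ASR → sampling → typing → report.

A single config drives the whole chain; every random draw derives from the
config seed, so a rerun with the same config is byte-identical.  Output
layout under the configured directory:

    ancestors/   most-probable sequences (alignment coordinates + ungapped)
    samples/     Monte-Carlo ancestor sets, one FASTA per node
    reports/     posterior TSVs, confidence summary, report.json, manifest
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (AA_ORDER, ProteinAlignment, map_reference_positions,
                        read_alignment)
from .classify import SiteRules, classify_catalytic_profile, partition_ancestor_set
from .likelihood import estimate_gamma_shape, optimize_branch_lengths
from .models import build_model
from .reconstruct import all_marginal_posteriors, most_probable_sequence
from .sampling import sample_ancestors, summarize_site_variability
from .trees import PhyloTree, TreeError, read_tree

CONFIG_VERSION = 1


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    alignment: str
    tree: str
    reference_id: str
    output_dir: str
    seed: int
    model: str = "WAG"
    frequency_mode: str = "model"
    alpha: float | str | None = "estimate"   # number, "estimate", or None
    gamma_k: int = 4
    fix_branch_lengths: bool = True
    root_on: str | None = None
    target_nodes: list[str] | None = None    # None = every internal node
    n_samples: int = 5000
    thresholds: list[float] = field(default_factory=lambda: [0.2, 0.5])
    present_threshold: float = 0.5
    rules: SiteRules = field(default_factory=SiteRules)
    config_version: int = CONFIG_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("config_version", CONFIG_VERSION) != CONFIG_VERSION:
            raise PipelineError(
                f"unsupported config_version {d.get('config_version')}")
        rules = SiteRules.from_dict(d["rules"]) if "rules" in d else SiteRules()
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__
                 and k != "rules"}
        if "seed" not in known:
            raise PipelineError("config must set a seed (sampling is requested)")
        return cls(rules=rules, **known)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "rules"}
        d["rules"] = self.rules.to_dict()
        return d


@dataclass
class RunReport:
    nodes: dict[str, dict]
    model: str
    alpha: float | None
    seed: int
    provenance: dict

    def to_json(self) -> str:
        payload = {"nodes": self.nodes, "model": self.model,
                   "alpha": self.alpha, "seed": self.seed,
                   "provenance": self.provenance}
        return json.dumps(payload, indent=1, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _posterior_tsv(post, path: Path) -> None:
    df = pd.DataFrame(post.probs, columns=list(AA_ORDER))
    df.insert(0, "site", np.arange(1, post.length + 1))
    df.insert(1, "masked", post.gap_mask.astype(int))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig,
                 aln: ProteinAlignment | None = None,
                 tree: PhyloTree | None = None) -> RunReport:
    """Execute the full analysis; returns the report and writes all outputs."""
    if aln is None:
        aln = read_alignment(config.alignment)
    if tree is None:
        tree = read_tree(config.tree, root_on=config.root_on)
    missing = [n for n in tree.leaf_names() if n not in aln.ids]
    if missing:
        raise PipelineError(f"tree leaves missing from the alignment: {missing}")

    labels = config.rules.all_labels()
    residue_numbers = [int(p) for p in labels]
    sitemap = map_reference_positions(aln, config.reference_id,
                                      residue_numbers, labels)

    alpha = config.alpha
    if alpha == "estimate":
        base = build_model(config.model, config.frequency_mode, aln)
        est = estimate_gamma_shape(tree, aln, base, K=config.gamma_k)
        alpha = est.alpha
    model = build_model(config.model, config.frequency_mode, aln,
                        alpha=alpha, K=config.gamma_k)
    if not config.fix_branch_lengths:
        tree, _ = optimize_branch_lengths(tree, aln, model)

    targets = config.target_nodes
    if targets is None:
        targets = sorted(tree.names[i] for i in tree.internal_indices())
    posts = all_marginal_posteriors(tree, aln, model, nodes=targets,
                                    present_threshold=config.present_threshold)

    out = Path(config.output_dir)
    for sub in ("ancestors", "samples", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    nodes_report: dict[str, dict] = {}
    conf_rows = []
    for i, name in enumerate(targets):
        post = posts[name]
        mp = most_probable_sequence(post)
        aset = sample_ancestors(post, config.n_samples, config.thresholds,
                                seed=config.seed + i)
        profile = classify_catalytic_profile(mp.sequence, sitemap, config.rules)
        part = partition_ancestor_set(aset, sitemap, config.rules)
        variability = summarize_site_variability(aset, sitemap)

        with open(out / "ancestors" / f"{name}.fasta", "w") as fh:
            fh.write(f">{name}|aligned\n{mp.sequence}\n"
                     f">{name}|ungapped\n{mp.ungapped()}\n")
        aset.to_fasta(out / "samples" / f"{name}.fasta")
        _posterior_tsv(post, out / "reports" / f"posterior_{name}.tsv")

        nodes_report[name] = {
            "sequence": mp.sequence,
            "mean_confidence": round(mp.mean_confidence, 6),
            "n_masked_sites": int(post.gap_mask.sum()),
            "catalytic_residues": profile.residues,
            "type_label": profile.type_label,
            "mn_site": profile.mn_site,
            "has_catalytic_trp": profile.has_catalytic_trp,
            "subset_fractions": part.subset_fractions,
            "type_fractions": part.type_fractions,
            "site_variability": variability,
        }
        conf_rows.append({"node": name,
                          "mean_confidence": mp.mean_confidence,
                          "n_masked_sites": int(post.gap_mask.sum())})

    pd.DataFrame(conf_rows).to_csv(out / "reports" / "confidence.tsv",
                                   sep="\t", index=False, float_format="%.6f")
    provenance = {
        "config": config.to_dict(),
        "package_version": __version__,
        "alpha_used": None if alpha is None else float(alpha),
    }
    report = RunReport(nodes_report, config.model,
                       None if alpha is None else float(alpha),
                       config.seed, provenance)
    (out / "reports" / "report.json").write_text(report.to_json())
    manifest = {"config": config.to_dict(), "report_sha256": report.digest(),
                "package_version": __version__}
    (out / "reports" / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return report
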