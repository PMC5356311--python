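"""Monte-Carlo sampling of alternative ancestral sequences ("near-ancestors").

At each unmasked site, residues whose posterior reaches a fraction θ of the
site's maximum posterior are eligible, and one is drawn with probability
proportional to its posterior among the eligibles.  Sampling runs once per
threshold (the requested total is split across thresholds) and the pooled
draws, always including the most-probable sequence, form the ancestor set.
With θ = 1 only the argmax survives, so every sample equals the
most-probable sequence; lower thresholds admit progressively more
posterior-supported variation.

Reproducibility: one seeded generator per node; uniforms are consumed
samples-outermost, sites in column order, so identical
(posteriors, n, thresholds, seed) give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AA_ORDER, GAP, SiteMap
from .reconstruct import AncestralSequence, PosteriorMatrix, most_probable_sequence


class SamplingError(ValueError):
    pass


@dataclass
class AncestorSet:
    """Sampled alternative ancestors for one node, plus the MAP sequence."""

    node: str
    most_probable: AncestralSequence
    samples: list[str]
    log_probs: list[float]
    sample_threshold: list[float]      # θ under which each sample was drawn
    thresholds: list[float]
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        assert self.most_probable.sequence in self.samples

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, (seq, lp) in enumerate(zip(self.samples, self.log_probs)):
                fh.write(f">{self.node}|sample_{k}|logP={lp:.6f}\n{seq}\n")


def _eligible(probs_row: np.ndarray, theta: float) -> np.ndarray:
    return probs_row >= theta * probs_row.max()


def sample_ancestors(post: PosteriorMatrix, n: int, thresholds: list[float],
                     seed: int) -> AncestorSet:
    """Draw ``n`` sequences from per-site posteriors under relative thresholds.

    The total is split across thresholds (the first threshold takes the
    remainder).  If the most-probable sequence is not among the draws it
    replaces the first one, so the set has exactly ``n`` members and always
    contains the most-probable ancestor.
    """
    if n < 1:
        raise SamplingError(f"need at least one sample, got n={n}")
    if not thresholds:
        raise SamplingError("no thresholds given")
    for th in thresholds:
        if not (0.0 < th <= 1.0):
            raise SamplingError(f"threshold {th} outside (0, 1]")
    map_seq = most_probable_sequence(post)
    L = post.length
    unmasked = np.flatnonzero(~post.gap_mask)
    aa = np.array(list(AA_ORDER))

    rng = np.random.default_rng(seed)
    base = n // len(thresholds)
    counts = [base] * len(thresholds)
    counts[0] += n - base * len(thresholds)

    samples: list[str] = []
    log_probs: list[float] = []
    sample_theta: list[float] = []
    for theta, n_th in zip(thresholds, counts):
        if n_th == 0:
            continue
        # per-site renormalized eligible distributions under this threshold
        cums, choices, raw_p = [], [], []
        for s in unmasked:
            row = post.probs[s]
            elig = np.flatnonzero(_eligible(row, theta))
            p = row[elig] / row[elig].sum()
            cums.append(np.cumsum(p))
            choices.append(elig)
            raw_p.append(row[elig])
        u = rng.random((n_th, len(unmasked)))
        chars = np.full((n_th, L), GAP, dtype="<U1")
        lp = np.zeros(n_th)
        for j, s in enumerate(unmasked):
            pick = np.searchsorted(cums[j], u[:, j], side="right")
            pick = np.minimum(pick, len(cums[j]) - 1)
            chars[:, s] = aa[choices[j][pick]]
            lp += np.log(raw_p[j][pick])
        samples.extend("".join(row) for row in chars)
        log_probs.extend(lp.tolist())
        sample_theta.extend([theta] * n_th)

    if map_seq.sequence not in samples:
        samples[0] = map_seq.sequence
        log_probs[0] = float(np.log(post.site_max()[unmasked]).sum())
    return AncestorSet(post.node, map_seq, samples, log_probs, sample_theta,
                       list(thresholds), n, seed)


def check_eligibility(aset: AncestorSet, post: PosteriorMatrix) -> bool:
    """Scan every sample against the posteriors: no residue may violate the
    threshold it was drawn under (the MAP sequence trivially satisfies all)."""
    unmasked = np.flatnonzero(~post.gap_mask)
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    for seq, theta in zip(aset.samples, aset.sample_threshold):
        if seq == aset.most_probable.sequence:
            continue
        for s in unmasked:
            row = post.probs[s]
            if row[idx[seq[s]]] < theta * row.max():
                return False
    return True


def summarize_site_variability(aset: AncestorSet, sites: SiteMap
                               ) -> dict[str, dict[str, float] | None]:
    """Residue frequencies across the sample at each named position.

    A position mapped to a masked (ancestrally absent) site is reported as
    ``None``.  Frequencies at each reported position sum to 1.
    """
    if not aset.samples:
        raise SamplingError("empty ancestor set")
    out: dict[str, dict[str, float] | None] = {}
    for pos in sites.positions:
        col = pos.column
        residues = [seq[col] for seq in aset.samples]
        if all(r == GAP for r in residues):
            out[pos.label] = None
            continue
        freqs: dict[str, float] = {}
        for r in residues:
            freqs[r] = freqs.get(r, 0.0) + 1.0
        total = sum(freqs.values())
        out[pos.label] = {r: c / total for r, c in sorted(freqs.items())}
    return out


def variability_table(summary: dict[str, dict[str, float] | None]) -> pd.DataFrame:
    rows = []
    for label, freqs in summary.items():
        if freqs is None:
            rows.append({"position": label, "residue": "absent in ancestor",
                         "frequency": np.nan})
        else:
            for r, f in freqs.items():
                rows.append({"position": label, "residue": r, "frequency": f})
    return pd.DataFrame(rows, columns=["position", "residue", "frequency"])
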