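"""Latent-space variant generation and screening.

New candidate sequences are drawn from the neighborhood of a
high-fitness reference: sample z = mu_ref + scale * sigma_ref * eps
around the reference's posterior, decode each point to its argmax
residue sequence, score global/local identity to the reference, predict
fitness with the fitted GP, and keep variants inside a strict fitness
window (e.g. above the best natural T50 but below an upper guard).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import DEFAULT_ALPHABET
from .gp import GpModel
from .identity import global_identity, local_identity
from .vae import TVAE, LatentGaussian


@dataclass
class VariantRecord:
    id: str
    sequence: str  # aligned representation (may contain gaps)
    predicted_fitness: float
    global_identity: float
    local_identity: float

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


def sample_around(ref: LatentGaussian, n: int, scale: float, seed: int) -> np.ndarray:
    """n latent points mu_ref + scale * sigma_ref * eps (seeded stream).

    scale=1 reproduces the reference posterior; scale=0 collapses onto
    its mean.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n, ref.d))
    return ref.mu + scale * ref.sigma * eps


def realize_sequences(latents: np.ndarray, model: TVAE) -> list[str]:
    """Decode latent points to argmax residue strings (aligned, with gaps)."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    probs = model.decode(latents)
    rows = np.argmax(probs, axis=2)
    return [DEFAULT_ALPHABET.decode(row) for row in rows]


def generate_variants(model: TVAE, gp: GpModel, ref: LatentGaussian,
                      ref_sequence: str, n: int = 10000, scale: float = 1.0,
                      seed: int = 42) -> list[VariantRecord]:
    """Sample, decode, score identity to the reference and predict fitness."""
    latents = sample_around(ref, n, scale, seed)
    seqs = realize_sequences(latents, model)
    means, _ = gp.predict(latents)
    records = []
    for k, (seq, fit) in enumerate(zip(seqs, means), start=1):
        records.append(VariantRecord(
            id=f"Generate_{k}",
            sequence=seq,
            predicted_fitness=float(fit),
            global_identity=global_identity(seq, ref_sequence),
            local_identity=local_identity(seq, ref_sequence),
        ))
    return records


def screen(variants: list[VariantRecord], lower: float, upper: float
           ) -> list[VariantRecord]:
    """Keep variants with lower < predicted fitness < upper (strict)."""
    if not lower < upper:
        raise ValueError("screen window requires lower < upper")
    return [v for v in variants if lower < v.predicted_fitness < upper]


def summarize(variants: list[VariantRecord]) -> dict:
    """Count plus mean/max of both identity measures."""
    if not variants:
        return {"count": 0}
    gi = np.array([v.global_identity for v in variants])
    li = np.array([v.local_identity for v in variants])
    return {
        "count": len(variants),
        "mean_global_identity": float(gi.mean()),
        "max_global_identity": float(gi.max()),
        "mean_local_identity": float(li.mean()),
        "max_local_identity": float(li.max()),
    }


def write_report_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpredicted_fitness\tglobal_identity\tlocal_identity\n")
        for v in variants:
            fh.write(f"{v.id}\t{v.predicted_fitness:.4f}\t"
                     f"{v.global_identity:.4f}\t{v.local_identity:.4f}\n")


def read_report_tsv(path: str | Path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a variant report")
        for line in fh:
            name, fit, gi, li = line.rstrip("\n").split("\t")
            records.append(VariantRecord(name, "", float(fit), float(gi), float(li)))
    return records


def write_variants_fasta(variants: list[VariantRecord], path: str | Path) -> None:
    """FASTA output of the ungapped generated sequences."""
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.id}\n{v.ungapped}\n")
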