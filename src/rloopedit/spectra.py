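"""Trinucleotide mutation spectra, signature extraction and similarity.

Substitutions are normalised to the pyrimidine convention: a mutation whose
reference base is a purine is reverse-complemented (together with its
flanking context) so that every channel has C or T at the centre.  The 96
channels follow the conventional order: six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), each crossed with the 16 5'/3' flanking
base pairs in alphabetical order, written ``5'[ref>alt]3'`` (e.g.
``T[C>T]A``).

Signature extraction is multiplicative-update non-negative matrix
factorisation under the generalised Kullback-Leibler divergence, run with
several seeded restarts; the returned signature matrix has columns summing
to one with exposures rescaled to compensate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import reverse_complement

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

CHANNELS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
]
_CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


@dataclass
class SubstitutionCall:
    """Classification of one SNV in pyrimidine-normalised trinucleotide context."""

    substitution: str  # one of SUBSTITUTION_CLASSES
    channel: str  # e.g. "T[C>T]A"
    pyrimidine_strand: str  # '+' if ref base was a pyrimidine on the + strand
    is_tcw: bool
    is_cpg: bool


def classify_substitution(
    contig: str, position: int, ref: str, alt: str, genome: dict[str, str]
) -> SubstitutionCall:
    """Classify a single SNV (0-based position) in trinucleotide context.

    ``is_tcw`` is true iff the normalised context is T[C>N]A or T[C>N]T,
    the APOBEC hotspot motif; ``is_cpg`` iff a C centre is followed by G.
    """
    seq = genome[contig]
    if not (1 <= position <= len(seq) - 2):
        raise ValueError(
            f"position {contig}:{position} too close to contig edge for "
            "trinucleotide context"
        )
    context = seq[position - 1 : position + 2].upper()
    if context[1] != ref:
        raise ValueError(
            f"ref {ref} does not match genome base {context[1]} at "
            f"{contig}:{position}"
        )
    if ref in PYRIMIDINES:
        strand = "+"
    else:
        strand = "-"
        context = reverse_complement(context)
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
    substitution = f"{ref}>{alt}"
    channel = f"{context[0]}[{substitution}]{context[2]}"
    is_tcw = ref == "C" and context[0] == "T" and context[2] in "AT"
    is_cpg = ref == "C" and context[2] == "G"
    return SubstitutionCall(substitution, channel, strand, is_tcw, is_cpg)


def classify_all(mutations: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Classify every mutation; returns the input with classification columns added."""
    calls = []
    for i, row in enumerate(mutations.itertuples(index=False)):
        try:
            calls.append(
                classify_substitution(row.contig, row.position, row.ref, row.alt, genome)
            )
        except ValueError as err:
            raise ValueError(f"mutation {i}: {err}") from err
    out = mutations.copy().reset_index(drop=True)
    out["substitution"] = [c.substitution for c in calls]
    out["channel"] = [c.channel for c in calls]
    out["pyrimidine_strand"] = [c.pyrimidine_strand for c in calls]
    out["is_tcw"] = [c.is_tcw for c in calls]
    out["is_cpg"] = [c.is_cpg for c in calls]
    return out


def build_96_spectrum(
    mutations: pd.DataFrame, genome: dict[str, str]
) -> tuple[pd.Series, pd.Series]:
    """96-channel spectrum plus a 7-class summary (CpG / non-CpG C>T split).

    Returns ``(spectrum, summary)``: the spectrum is a Series over the 96
    canonical channels whose values sum to the number of input SNVs; the
    summary splits C>T into CpG and non-CpG classes.
    """
    classified = classify_all(mutations, genome)
    counts = np.zeros(96, dtype=np.int64)
    for ch in classified["channel"]:
        counts[_CHANNEL_INDEX[ch]] += 1
    spectrum = pd.Series(counts, index=CHANNELS, name="count")

    summary_index = ["C>A", "C>G", "C>T at CpG", "C>T other", "T>A", "T>C", "T>G"]
    summary = pd.Series(0, index=summary_index, dtype=np.int64)
    for sub, cpg in zip(classified["substitution"], classified["is_cpg"]):
        if sub == "C>T":
            summary["C>T at CpG" if cpg else "C>T other"] += 1
        else:
            summary[sub] += 1
    return spectrum, summary


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors; in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _nmf_single(
    V: np.ndarray, rank: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = V.shape
    W = rng.uniform(0.1, 1.0, size=(n, rank))
    H = rng.uniform(0.1, 1.0, size=(rank, m))
    eps = 1e-12
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= W.T @ (V / WH) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= (V / WH) @ H.T / (H.sum(axis=1)[None, :] + eps)
        obj = _kl_divergence(V, W @ H + eps)
        history.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            break
        prev = obj
    return W, H, history


def extract_signatures_nmf(
    spectra: np.ndarray,
    rank: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """De novo signature extraction by KL-NMF with seeded restarts.

    ``spectra`` is channels x samples (rows 96 in typical use).  Returns
    ``(signatures, exposures, objective_history)`` for the best restart by
    final divergence (ties broken by lowest restart index); signature
    columns sum to one.
    """
    V = np.asarray(spectra, dtype=float)
    if np.any(V < 0):
        raise ValueError("spectra must be non-negative")
    if V.sum() == 0:
        raise ValueError("cannot factorise an all-zero matrix")
    if rank >= min(V.shape):
        raise ValueError("rank must be smaller than both matrix dimensions")
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for i in range(n_restarts):
        W, H, hist = _nmf_single(
            V, rank, np.random.default_rng(seeds[i]), max_iter, tol
        )
        if best is None or hist[-1] < best[2][-1]:
            best = (W, H, hist)
    W, H, hist = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return W, H, hist


def match_signatures(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[list[int], list[float]]:
    """Greedy best-cosine pairing of estimated signature columns to truth columns."""
    K = truth.shape[1]
    sims = np.array(
        [
            [cosine_similarity(estimated[:, i], truth[:, j]) for j in range(K)]
            for i in range(estimated.shape[1])
        ]
    )
    assignment = [-1] * K
    scores = [0.0] * K
    used_rows: set[int] = set()
    for _ in range(min(K, estimated.shape[1])):
        masked = sims.copy()
        masked[list(used_rows), :] = -1
        masked[:, [j for j in range(K) if assignment[j] >= 0]] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        assignment[j] = int(i)
        scores[j] = float(sims[i, j])
        used_rows.add(int(i))
    return assignment, scores


def spectrum_to_tsv(spectrum: pd.Series, path) -> None:
    spectrum.rename_axis("channel").to_frame().to_csv(path, sep="\t")


def signatures_to_tsv(signatures: np.ndarray, path) -> None:
    df = pd.DataFrame(
        signatures,
        index=CHANNELS[: signatures.shape[0]],
        columns=[f"signature_{k + 1}" for k in range(signatures.shape[1])],
    )
    df.rename_axis("channel").to_csv(path, sep="\t")
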