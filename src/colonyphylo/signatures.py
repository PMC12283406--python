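"""Mutational-signature refitting on the 96 trinucleotide channels.

Spectra are counts over the 96 pyrimidine-strand single-base-substitution
channels, ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with
5' then 3' flanking bases alphabetical within each substitution — the
conventional lexicographic layout written in the signature TSV header.

Refitting solves a non-negative least squares problem against a reference
catalog; per-mutation signature attribution follows from the fitted
exposures and each signature's mass on the mutation's channel.

The packaged default catalog (``default_reference_signatures``) contains
*synthetic* parametric analogs of the clock-like signatures SBS1 (C>T
spikes at NpCpG) and SBS5 (flat, broad), plus a melphalan-like signature
concentrated on T>A with non-CpG C>T — adequate for simulation and tests,
not a substitute for a curated catalog, which can be supplied as TSV.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls

PYRIMIDINES = "CT"
BASES = "ACGT"
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
CHANNELS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a substitution with trinucleotide context to its 96-channel label.

    ``context`` is the 3-mer centered on the reference base. Purine-strand
    calls are reverse-complemented onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref not in PYRIMIDINES:
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
        context = _revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"invalid substitution channel {label!r}")
    return label


def decode_channel(channel: str) -> tuple[str, str, str]:
    """Inverse of :func:`channel_of`: returns (ref, alt, context)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


def count_contexts(mutations: pd.DataFrame) -> pd.Series:
    """96-channel spectrum from a table with ref/alt/trinucleotide_context.

    Total count is preserved; purine-strand rows are folded onto the
    pyrimidine strand.
    """
    counts = np.zeros(96, dtype=float)
    if len(mutations):
        for ref, alt, ctx in zip(mutations["ref"], mutations["alt"],
                                 mutations["trinucleotide_context"]):
            counts[_CHANNEL_INDEX[channel_of(ref, alt, ctx)]] += 1
    return pd.Series(counts, index=CHANNELS_96, name="count")


def default_reference_signatures() -> pd.DataFrame:
    """Synthetic reference catalog: SBS1, SBS5 and a melphalan-like SBSC.

    Each column sums to 1. See the module docstring for provenance.
    """
    sig = pd.DataFrame(0.0, index=CHANNELS_96, columns=["SBS1", "SBS5", "SBSC"])

    # SBS1: deamination of methylated cytosine -> C>T at NpCpG
    for five in BASES:
        sig.loc[f"{five}[C>T]G", "SBS1"] = 0.22
    rest = [c for c in CHANNELS_96 if sig.loc[c, "SBS1"] == 0.0]
    sig.loc[rest, "SBS1"] = (1.0 - 0.88) / len(rest)

    # SBS5: flat clock-like background, mildly enriched for T>C
    w = pd.Series(1.0, index=CHANNELS_96)
    w[[c for c in CHANNELS_96 if "[T>C]" in c]] = 2.0
    w[[c for c in CHANNELS_96 if "[C>T]" in c]] = 1.5
    sig["SBS5"] = w / w.sum()

    # melphalan-like: alkylator adducts, T>A-dominated with non-CpG C>T
    w = pd.Series(0.05, index=CHANNELS_96)
    w[[c for c in CHANNELS_96 if "[T>A]" in c]] = 4.0
    w[[c for c in CHANNELS_96 if "[C>T]" in c and not c.endswith("G")]] = 1.5
    sig["SBSC"] = w / w.sum()
    return sig


def read_signature_table(path) -> pd.DataFrame:
    """Read a COSMIC-style TSV (96 channel rows x signature columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ValueError(f"signature table lacks {len(missing)} channels")
    df = df.loc[CHANNELS_96]
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1 (+/- 1e-6)")
    return df


def write_signature_table(signatures: pd.DataFrame, path) -> None:
    signatures.loc[CHANNELS_96].to_csv(path, sep="\t", index_label="channel")


def fit_exposures(
    spectrum: pd.Series,
    reference_set: pd.DataFrame,
    min_exposure: float = 1.0,
) -> tuple[pd.Series, float]:
    """Non-negative least-squares refit of a spectrum onto a catalog.

    Returns (exposures in mutation counts, L2 residual). Exposures below
    ``min_exposure`` mutations are zeroed to stabilize downstream
    per-mutation posteriors.
    """
    y = np.asarray(spectrum.reindex(reference_set.index).fillna(0.0), dtype=float)
    if y.sum() <= 0:
        raise ValueError("cannot fit an all-zero spectrum")
    A = reference_set.to_numpy(dtype=float)
    coef, residual = nnls(A, y)
    coef[coef < min_exposure] = 0.0
    return pd.Series(coef, index=reference_set.columns, name="exposure"), float(residual)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


class NoveltyResult(NamedTuple):
    status: str            # "known" | "novel"
    best_match: str | None
    similarity: float


NOVELTY_THRESHOLD = 0.80  # max cosine <= threshold => new signature


def classify_novelty(candidate: pd.Series, catalog: pd.DataFrame,
                     threshold: float = NOVELTY_THRESHOLD) -> NoveltyResult:
    """A candidate signature is novel iff its best catalog cosine is <= threshold."""
    sims = {name: cosine_similarity(candidate, catalog[name]) for name in catalog.columns}
    best = max(sims, key=lambda k: sims[k])
    if sims[best] <= threshold:
        return NoveltyResult("novel", None, sims[best])
    return NoveltyResult("known", best, sims[best])


def per_mutation_probability(
    channel: str,
    exposures: pd.Series,
    reference_set: pd.DataFrame,
) -> pd.Series:
    """Posterior P(signature | channel) under the fitted exposure mixture."""
    mass = reference_set.loc[channel] * exposures
    total = mass.sum()
    if total <= 0:
        raise ValueError(f"no fitted signature has mass on channel {channel!r}")
    return mass / total


def attribute_mutations(
    mutations: pd.DataFrame,
    exposures: pd.Series,
    reference_set: pd.DataFrame,
) -> pd.DataFrame:
    """Per-mutation signature posteriors plus the maximum-posterior call.

    Returns the input table with one ``p_<signature>`` column per catalog
    signature and ``assigned_signature`` / ``assigned_probability`` columns.
    """
    out = mutations.copy()
    names = list(reference_set.columns)
    post = np.zeros((len(out), len(names)))
    cache: dict[str, np.ndarray] = {}
    for i, (ref, alt, ctx) in enumerate(zip(out["ref"], out["alt"],
                                            out["trinucleotide_context"])):
        ch = channel_of(ref, alt, ctx)
        if ch not in cache:
            cache[ch] = per_mutation_probability(ch, exposures, reference_set).to_numpy()
        post[i] = cache[ch]
    for j, name in enumerate(names):
        out[f"p_{name}"] = post[:, j]
    idx = post.argmax(axis=1) if len(out) else np.array([], dtype=int)
    out["assigned_signature"] = [names[j] for j in idx]
    out["assigned_probability"] = post[np.arange(len(out)), idx] if len(out) else []
    return out
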