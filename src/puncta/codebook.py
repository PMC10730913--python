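"""Combinatorial barcode codebooks.

Each feature (gene or control) is encoded as a constant-weight binary
codeword over an ``n_cycles x n_channels`` grid of imaging rounds and color
channels: a bit is "on" when the feature fluoresces in that cycle/channel.
Codewords are kept at a minimum pairwise Hamming distance so that single-bit
errors (a dropped or spurious signal) do not turn one codeword into another.

Three control classes share the codeword constraints with genes:

* ``negative_control_probe`` — a probe that targets non-biological sequence;
  its detections measure assay-level non-specific binding.
* ``negative_control_codeword`` — a codeword with no corresponding probe;
  calls to it measure the decoder's false-assignment rate and drive the
  Phred-style quality calibration.
* ``unassigned`` — a valid codeword simply not used by the panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

CATEGORY_GENE = "gene"
CATEGORY_NEG_PROBE = "negative_control_probe"
CATEGORY_NEG_CODEWORD = "negative_control_codeword"
CATEGORY_UNASSIGNED = "unassigned"

CATEGORIES = (
    CATEGORY_GENE,
    CATEGORY_NEG_PROBE,
    CATEGORY_NEG_CODEWORD,
    CATEGORY_UNASSIGNED,
)

#: control categories that have physical probes (emit signal in the sample)
PROBE_CATEGORIES = (CATEGORY_GENE, CATEGORY_NEG_PROBE)


class CodebookInfeasibleError(RuntimeError):
    """Raised when the randomized search cannot place all requested codes."""


@dataclass
class Codebook:
    """An ordered set of binary codewords with per-code metadata.

    Parameters
    ----------
    codes
        ``(n_codes, n_cycles, n_channels)`` uint8 array in {0, 1}.
    names
        Unique feature name per code.
    categories
        Per-code category, one of :data:`CATEGORIES`.
    """

    codes: np.ndarray
    names: list[str]
    categories: list[str]
    weight: int
    min_hamming: int
    seed: int | None = None
    _name_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 3:
            raise ValueError("codes must be (n_codes, n_cycles, n_channels)")
        if len(self.names) != len(self.codes) or len(self.categories) != len(self.codes):
            raise ValueError("names/categories length must match number of codes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")
        self._name_index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_codes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.codes.shape[1]

    @property
    def n_channels(self) -> int:
        return self.codes.shape[2]

    @property
    def n_bits(self) -> int:
        return self.n_cycles * self.n_channels

    def flat_codes(self) -> np.ndarray:
        """Codes flattened row-major (cycle-then-channel) to (n_codes, n_bits)."""
        return self.codes.reshape(self.n_codes, -1)

    def index_of(self, name: str) -> int:
        return self._name_index[name]

    def category_indices(self, category: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.categories) if c == category], dtype=int
        )

    def category_counts(self) -> dict[str, int]:
        return {cat: self.categories.count(cat) for cat in CATEGORIES}

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the codebook as JSON listing each code's [cycle, channel] on-bits."""
        entries = []
        for i in range(self.n_codes):
            on = np.argwhere(self.codes[i] == 1)
            entries.append(
                {
                    "name": self.names[i],
                    "category": self.categories[i],
                    "code": [[int(cy), int(ch)] for cy, ch in on],
                }
            )
        payload = {
            "n_cycles": self.n_cycles,
            "n_channels": self.n_channels,
            "weight": self.weight,
            "min_hamming": self.min_hamming,
            "seed": self.seed,
            "codewords": entries,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        n_cy, n_ch = payload["n_cycles"], payload["n_channels"]
        entries = payload["codewords"]
        codes = np.zeros((len(entries), n_cy, n_ch), dtype=np.uint8)
        names, categories = [], []
        for i, e in enumerate(entries):
            for cy, ch in e["code"]:
                codes[i, cy, ch] = 1
            names.append(e["name"])
            categories.append(e["category"])
        return cls(
            codes=codes,
            names=names,
            categories=categories,
            weight=payload["weight"],
            min_hamming=payload["min_hamming"],
            seed=payload.get("seed"),
        )

    def validate(self) -> None:
        """Assert all structural invariants; raise ValueError on violation."""
        w = self.flat_codes().sum(axis=1)
        if not np.all(w == self.weight):
            raise ValueError("not all codes have the declared weight")
        if self.n_codes >= 2 and min_pairwise_hamming(self) < self.min_hamming:
            raise ValueError("minimum pairwise Hamming distance violated")


def min_pairwise_hamming(codebook: Codebook) -> int:
    """Minimum Hamming distance over all unordered pairs of flattened codes."""
    if codebook.n_codes < 2:
        raise ValueError("need at least 2 codes")
    d = pdist(codebook.flat_codes().astype(float), metric="hamming")
    return int(round(d.min() * codebook.n_bits))


def build_codebook(
    n_genes: int,
    n_neg_probe: int = 0,
    n_neg_codeword: int = 0,
    n_unassigned: int = 0,
    n_cycles: int = 15,
    n_channels: int = 4,
    weight: int = 4,
    min_hamming: int = 4,
    seed: int = 0,
    max_attempts_per_code: int = 2000,
) -> Codebook:
    """Generate a constant-weight codebook by seeded randomized greedy search.

    Codes are drawn uniformly at random among weight-``weight`` binary vectors
    of length ``n_cycles * n_channels`` and accepted when at Hamming distance
    >= ``min_hamming`` from every previously accepted code. Categories are
    assigned in declared counts, genes first, then negative-control probes,
    negative-control codewords, and unassigned codes — all four classes obey
    the same weight/distance constraints.

    Raises
    ------
    CodebookInfeasibleError
        If a code cannot be placed within ``max_attempts_per_code`` draws.
    """
    n_bits = n_cycles * n_channels
    if weight > n_bits:
        raise ValueError("weight exceeds number of bits")
    if min(n_genes, n_neg_probe, n_neg_codeword, n_unassigned) < 0:
        raise ValueError("code counts must be nonnegative")
    n_total = n_genes + n_neg_probe + n_neg_codeword + n_unassigned
    if n_total == 0:
        raise ValueError("requested an empty codebook")

    rng = np.random.default_rng(seed)
    accepted = np.zeros((n_total, n_bits), dtype=np.uint8)
    n_acc = 0
    while n_acc < n_total:
        placed = False
        for _ in range(max_attempts_per_code):
            cand = np.zeros(n_bits, dtype=np.uint8)
            cand[rng.choice(n_bits, size=weight, replace=False)] = 1
            if n_acc == 0:
                dmin = n_bits
            else:
                dmin = int((accepted[:n_acc] != cand).sum(axis=1).min())
            if dmin >= min_hamming:
                accepted[n_acc] = cand
                n_acc += 1
                placed = True
                break
        if not placed:
            raise CodebookInfeasibleError(
                f"codebook infeasible: placed {n_acc}/{n_total} codes "
                f"(weight={weight}, min_hamming={min_hamming}, n_bits={n_bits})"
            )

    names: list[str] = []
    categories: list[str] = []
    for count, cat, prefix in (
        (n_genes, CATEGORY_GENE, "Gene"),
        (n_neg_probe, CATEGORY_NEG_PROBE, "NegControlProbe"),
        (n_neg_codeword, CATEGORY_NEG_CODEWORD, "NegControlCodeword"),
        (n_unassigned, CATEGORY_UNASSIGNED, "Unassigned"),
    ):
        for i in range(count):
            names.append(f"{prefix}_{i:05d}")
            categories.append(cat)

    return Codebook(
        codes=accepted.reshape(n_total, n_cycles, n_channels),
        names=names,
        categories=categories,
        weight=weight,
        min_hamming=min_hamming,
        seed=seed,
    )
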