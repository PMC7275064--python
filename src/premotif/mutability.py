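"""Heptamer-context mutation-rate arithmetic.

The central object is the :class:`ERMTable`: for every 7-mer over ACGT it
stores three estimated relative mutation (ERM) rates, one for each possible
single-nucleotide change at the middle position.  Rates are dimensionless and
relative (only ratios matter), strictly positive, and typically span a very
wide dynamic range across contexts (CpG transitions and other hotspots sit
orders of magnitude above the coldest contexts).

Derived quantities implemented here:

* per-site mutability — the arithmetic mean of the three alternate-allele
  rates given the heptamer context of a position (circular or linear);
* hexamer-level mean mutability — the mean ERM rate over all 18 possible
  single-nucleotide changes in a hexamer, averaging uniformly over the
  unknown flanking bases needed to complete each heptamer context
  (``NNN[XXXXXX]NNN`` with each N weighted 1/4 per base);
* mutational-bias rescaling ``r -> r**beta`` (log-transform, scale by beta,
  inverse-transform), with ``beta=0`` giving uniform rates and ``beta=1``
  the original spectrum;
* descending mutability ranking of the 4096 hexamers with quintile labels
  (quintile 5 = most mutable fifth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_HEPTAMERS = 4 ** 7  # 16384
N_HEXAMERS = 4 ** 6  # 4096

__all__ = [
    "BASES",
    "N_HEPTAMERS",
    "N_HEXAMERS",
    "ERMTable",
    "HexamerRateTable",
    "ScoreTable",
    "encode_kmer",
    "decode_kmer",
    "seq_to_ints",
    "ints_to_seq",
    "site_rate",
    "hexamer_mean_rate",
    "hexamer_mean_rates",
    "rescale_bias",
    "rank_hexamers",
]


def encode_kmer(kmer: str) -> int:
    """Base-4 integer index of a k-mer (A=0, C=1, G=2, T=3; leftmost base
    is the most significant digit).  Raises on non-ACGT characters."""
    idx = 0
    for ch in kmer:
        try:
            idx = idx * 4 + _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}") from None
    return idx


def decode_kmer(idx: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append(BASES[(idx >> (2 * shift)) & 3])
    return "".join(out)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0..T=3, anything else -1).

    Lowercase is accepted and upper-cased; N and other ambiguity codes map
    to -1 and are skipped by downstream k-mer counting.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def ints_to_seq(ints: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return bytes(lut[np.where(ints < 0, 4, ints)]).decode("ascii")


_POW4_7 = 4 ** np.arange(6, -1, -1)
_POW4_6 = 4 ** np.arange(5, -1, -1)


def kmer_indices(ints: np.ndarray, k: int, circular: bool = False) -> np.ndarray:
    """Indices of all overlapping k-mers of an encoded sequence.

    Linear sequences yield ``len - k + 1`` windows; circular sequences yield
    ``len`` windows (one anchored at every position).  Windows containing a
    negative code (N) get index -1.
    """
    n = len(ints)
    if circular:
        pos = (np.arange(n)[:, None] + np.arange(k)[None, :]) % n
    else:
        if n < k:
            return np.empty(0, dtype=np.int64)
        pos = np.arange(n - k + 1)[:, None] + np.arange(k)[None, :]
    win = ints[pos].astype(np.int64)
    bad = (win < 0).any(axis=1)
    idx = win @ (4 ** np.arange(k - 1, -1, -1))
    idx[bad] = -1
    return idx


@dataclass
class ERMTable:
    """Complete heptamer -> {3 alternate alleles} relative-rate table.

    ``rates`` has shape (16384, 4); entry ``[h, a]`` is the rate of mutating
    the middle base of heptamer ``h`` to base ``a``, and is NaN when ``a``
    equals the middle base (a change to self is not a mutation).
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_HEPTAMERS, 4):
            raise ValueError(f"rates must have shape ({N_HEPTAMERS}, 4)")
        mid = self.middle_bases()
        diag = self.rates[np.arange(N_HEPTAMERS), mid]
        if not np.all(np.isnan(diag)):
            raise ValueError("rate for alt == middle base must be absent (NaN)")
        off = self.rates[~np.isnan(self.rates)]
        if off.size != 3 * N_HEPTAMERS:
            missing = 3 * N_HEPTAMERS - off.size
            raise ValueError(f"incomplete table: {missing} (heptamer, alt) rates missing")
        if not np.all(off > 0):
            raise ValueError("all ERM rates must be strictly positive")

    @staticmethod
    def middle_bases() -> np.ndarray:
        """Middle-base code of every heptamer index (digit 4 of 7)."""
        return (np.arange(N_HEPTAMERS) >> 6) & 3

    @classmethod
    def uniform(cls, value: float = 1.0) -> "ERMTable":
        rates = np.full((N_HEPTAMERS, 4), float(value))
        rates[np.arange(N_HEPTAMERS), cls.middle_bases()] = np.nan
        return cls(rates)

    @classmethod
    def from_dict(cls, mapping: dict[tuple[str, str], float]) -> "ERMTable":
        rates = np.full((N_HEPTAMERS, 4), np.nan)
        for (hept, alt), rate in mapping.items():
            rates[encode_kmer(hept), _BASE_INDEX[alt]] = rate
        return cls(rates)

    def rate(self, heptamer: str, alt: str) -> float:
        """Rate of the middle base of ``heptamer`` mutating to ``alt``."""
        if len(heptamer) != 7:
            raise ValueError(f"heptamer must have length 7, got {heptamer!r}")
        if alt == heptamer[3]:
            raise ValueError(f"alt {alt!r} equals the middle base of {heptamer!r}")
        return float(self.rates[encode_kmer(heptamer), _BASE_INDEX[alt]])

    @property
    def site_mean(self) -> np.ndarray:
        """Per-heptamer arithmetic mean of the three alternate rates.

        Cached; tables are treated as immutable after construction.
        """
        cached = getattr(self, "_site_mean", None)
        if cached is None:
            cached = np.nansum(self.rates, axis=1) / 3.0
            object.__setattr__(self, "_site_mean", cached)
        return cached

    def to_frame(self) -> pd.DataFrame:
        hepts, alts, vals = [], [], []
        for h in range(N_HEPTAMERS):
            hstr = decode_kmer(h, 7)
            for a in range(4):
                if np.isnan(self.rates[h, a]):
                    continue
                hepts.append(hstr)
                alts.append(BASES[a])
                vals.append(self.rates[h, a])
        return pd.DataFrame({"heptamer": hepts, "alt": alts, "rate": vals})

    def dynamic_range(self) -> float:
        off = self.rates[~np.isnan(self.rates)]
        return float(off.max() / off.min())


def rescale_bias(erm: ERMTable, beta: float) -> ERMTable:
    """Rescale every rate ``r -> r**beta``.

    Equivalent to log-transforming, multiplying by the mutational-bias
    parameter beta, and inverse-transforming (the result is independent of
    the log base).  beta=1 returns the original spectrum, beta=0 uniform
    rates, beta in (0,1) a compressed and beta>1 an expanded dynamic range.
    Rank order is preserved for beta > 0.
    """
    if beta < 0:
        raise ValueError(f"bias parameter must be nonnegative, got {beta}")
    # preserve the NaN diagonal (nan ** 0 would be 1)
    return ERMTable(np.where(np.isnan(erm.rates), np.nan, erm.rates**beta))


def site_rate(seq: str | np.ndarray, pos: int, erm: ERMTable, circular: bool = True) -> float:
    """Mean ERM rate of the three possible changes at ``pos``.

    The heptamer context spans pos-3..pos+3.  Circular sequences wrap; for
    linear sequences the full context must exist within the sequence.
    """
    ints = seq_to_ints(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    n = len(ints)
    if circular:
        if n < 7:
            raise ValueError("circular sequence shorter than 7 nt has no unique heptamer context")
        window = ints[(pos + np.arange(-3, 4)) % n]
    else:
        if pos < 3 or pos > n - 4:
            raise ValueError(
                f"position {pos} lacks the +/-3 nt heptamer context in a linear sequence of length {n}"
            )
        window = ints[pos - 3 : pos + 4]
    if (window < 0).any():
        raise ValueError(f"heptamer context at position {pos} contains non-ACGT bases")
    hept = int(window.astype(np.int64) @ _POW4_7)
    return float(erm.site_mean[hept])


def hexamer_mean_rates(erm: ERMTable) -> np.ndarray:
    """Mean ERM rate of all 4096 hexamers, vectorised.

    For each hexamer, the 18 possible single-nucleotide changes (6 positions
    x 3 alternates) are averaged; each change's heptamer context is completed
    by averaging uniformly over the unknown flanking bases (positions of the
    +/-3 nt window that fall outside the hexamer).
    """
    rates = erm.rates
    hexes = np.arange(N_HEXAMERS, dtype=np.int64)
    total = np.zeros(N_HEXAMERS)
    alt_sum = np.nansum(rates, axis=1)  # sum over the 3 alternates
    for pos in range(6):
        lo = max(0, pos - 3)
        hi = min(5, pos + 3)
        left_unknown = max(0, 3 - pos)
        right_unknown = max(0, pos + 3 - 5)
        span = hi - lo + 1
        known = (hexes >> (2 * (5 - hi))) & (4 ** span - 1)
        n_flank = 4 ** (left_unknown + right_unknown)
        acc = np.zeros(N_HEXAMERS)
        for lf in range(4 ** left_unknown):
            for rf in range(4 ** right_unknown):
                hept = ((lf * 4 ** span + known) << (2 * right_unknown)) + rf
                acc += alt_sum[hept]
        total += acc / n_flank
    return total / 18.0


def hexamer_mean_rate(hexamer: str, erm: ERMTable) -> float:
    """Mean ERM rate of one hexamer (see :func:`hexamer_mean_rates`)."""
    if len(hexamer) != 6:
        raise ValueError(f"expected a hexamer, got {hexamer!r}")
    total = 0.0
    n = 0
    for pos in range(6):
        left_unknown = max(0, 3 - pos)
        right_unknown = max(0, pos + 3 - 5)
        lo = max(0, pos - 3)
        hi = min(5, pos + 3)
        core = hexamer[lo : hi + 1]
        flank_mean = 0.0
        n_flank = 0
        for lf in range(4 ** left_unknown):
            left = decode_kmer(lf, left_unknown) if left_unknown else ""
            for rf in range(4 ** right_unknown):
                right = decode_kmer(rf, right_unknown) if right_unknown else ""
                hept = left + core + right
                flank_mean += float(erm.site_mean[encode_kmer(hept)])
                n_flank += 1
        total += 3 * flank_mean / n_flank  # 3 alternates at this position
        n += 3
    return total / n


@dataclass
class HexamerRateTable:
    """Mean mutability and quintile label for all 4096 hexamers.

    ``quintile[h]`` is 1..5 with 5 = the most mutable fifth.  Quintiles
    partition the descending mean-rate ranking as evenly as possible
    (820 + 4x819 hexamers); ties are broken lexicographically.
    """

    mean_rate: np.ndarray
    quintile: np.ndarray = field(init=False)
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        if self.mean_rate.shape != (N_HEXAMERS,):
            raise ValueError("mean_rate must cover all 4096 hexamers")
        # descending by rate; ties broken by ascending hexamer index
        self.order = np.lexsort((np.arange(N_HEXAMERS), -self.mean_rate))
        rank = np.empty(N_HEXAMERS, dtype=np.int64)
        rank[self.order] = np.arange(N_HEXAMERS)
        bounds = np.cumsum([len(chunk) for chunk in np.array_split(np.arange(N_HEXAMERS), 5)])
        self.quintile = 5 - np.searchsorted(bounds, rank, side="right")

    @classmethod
    def from_erm(cls, erm: ERMTable) -> "HexamerRateTable":
        return cls(hexamer_mean_rates(erm))

    def most_mutable(self, n: int = 1) -> list[str]:
        return [decode_kmer(int(i), 6) for i in self.order[:n]]

    def least_mutable(self, n: int = 1) -> list[str]:
        return [decode_kmer(int(i), 6) for i in self.order[-n:][::-1]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hexamer": [decode_kmer(i, 6) for i in range(N_HEXAMERS)],
                "mean_rate": self.mean_rate,
                "quintile": self.quintile,
            }
        )


def rank_hexamers(hex_rates: HexamerRateTable) -> pd.DataFrame:
    """Hexamers in descending mean-rate order with quintile labels."""
    df = hex_rates.to_frame()
    return df.iloc[hex_rates.order].reset_index(drop=True)


@dataclass
class ScoreTable:
    """Partial mapping k-mer -> activity score (e.g. hexamer EI scores).

    Stored densely over all 4**k k-mers with NaN marking explicit absences;
    missing entries are reported, never silently imputed.
    """

    scores: np.ndarray
    k: int = 6
    name: str = "score"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (4 ** self.k,):
            raise ValueError(f"scores must have shape ({4 ** self.k},) for k={self.k}")

    @classmethod
    def from_dict(cls, mapping: dict[str, float], k: int = 6, name: str = "score") -> "ScoreTable":
        scores = np.full(4 ** k, np.nan)
        for kmer, val in mapping.items():
            if len(kmer) != k:
                raise ValueError(f"{kmer!r} is not a {k}-mer")
            scores[encode_kmer(kmer)] = val
        return cls(scores, k=k, name=name)

    def score(self, kmer: str) -> float:
        return float(self.scores[encode_kmer(kmer)])

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.scores).sum())

    def missing_kmers(self, limit: int | None = None) -> list[str]:
        idx = np.flatnonzero(np.isnan(self.scores))
        if limit is not None:
            idx = idx[:limit]
        return [decode_kmer(int(i), self.k) for i in idx]

    def to_frame(self) -> pd.DataFrame:
        idx = np.flatnonzero(self.present)
        return pd.DataFrame(
            {
                "hexamer" if self.k == 6 else "kmer": [decode_kmer(int(i), self.k) for i in idx],
                self.name: self.scores[idx],
            }
        )
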