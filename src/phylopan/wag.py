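"""The WAG amino-acid substitution model.

WAG (Whelan & Goldman 2001) is an empirical reversible model given by a
symmetric exchangeability matrix S and stationary frequencies pi. The rate
matrix is Q_ij = S_ij * pi_j (i != j), with rows summing to zero and
normalized so that one unit of branch length equals one expected
substitution per site. Transition probabilities P(t) = expm(Qt) are obtained
from the eigendecomposition of the symmetrized rate matrix, which is exact
and cheap for a 20-state reversible chain.

The numerical values live in ``data/wag.dat`` (residue order
ARNDCQEGHILKMFPSTWYV); the file's sha256 is pinned here so silent edits are
caught at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

WAG_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_WAG_SHA256 = "2d63e4012a28ffa27290d46d5eaeb87474a80dcab8cfc3cac621d4450fefa966"


def _load_wag_data() -> tuple[np.ndarray, np.ndarray]:
    text = (resources.files("phylopan") / "data" / "wag.dat").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _WAG_SHA256:
        raise RuntimeError("wag.dat checksum mismatch; model data was modified")
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.zeros((20, 20))
    for i, ln in enumerate(rows[:19], start=1):
        vals = [float(v) for v in ln.split()]
        for j, v in enumerate(vals):
            S[i, j] = S[j, i] = v
    freqs = np.array([float(v) for v in rows[19].split()])
    freqs = freqs / freqs.sum()
    return S, freqs


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model with unit-rate normalization."""

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alphabet: str = WAG_ALPHABET
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S, pi = self.exchangeabilities, self.frequencies
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.sum(pi * np.diag(Q))
        Q = Q / rate
        self.rate_matrix = Q
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (w, V, sq)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("time must be non-negative")
        w, V, sq = self._eig
        inner = (V * np.exp(w * t)) @ V.T
        P = (inner / sq[:, None]) * sq[None, :]
        return np.clip(P, 0.0, None)

    def index(self, residue: str) -> int:
        return self.alphabet.index(residue)

    def sample_stationary(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Sequence of state indices drawn from the stationary distribution."""
        return rng.choice(20, size=length, p=self.frequencies)

    def evolve_states(
        self, states: np.ndarray, t: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Evolve each site independently for time t (state indices in/out)."""
        P = self.transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(len(states))
        return np.array(
            [np.searchsorted(cum[s], x, side="right") for s, x in zip(states, u)],
            dtype=np.int64,
        )

    def states_to_str(self, states: np.ndarray) -> str:
        return "".join(self.alphabet[s] for s in states)

    def str_to_states(self, seq: str) -> np.ndarray:
        return np.array([self.alphabet.index(c) for c in seq], dtype=np.int64)


_WAG: SubstitutionModel | None = None


def wag_model() -> SubstitutionModel:
    """The packaged WAG model (cached)."""
    global _WAG
    if _WAG is None:
        S, pi = _load_wag_data()
        _WAG = SubstitutionModel(name="WAG", exchangeabilities=S, frequencies=pi)
    return _WAG
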