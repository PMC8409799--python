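"""Paillier additively homomorphic cryptosystem on native Python big integers.

The Paillier scheme encrypts a message ``m`` in ``[0, N)`` as
``c = g^m * r^N mod N^2`` for a random ``r`` coprime to ``N``, where
``N = p*q`` is a product of two large primes.  Multiplying two ciphertexts
modulo ``N^2`` adds the underlying plaintexts modulo ``N``, and raising a
ciphertext to a plaintext power multiplies the plaintext by that scalar.
Decryption computes ``m = L(c^lambda mod N^2) * mu mod N`` with
``L(x) = (x - 1) / N``, ``lambda = lcm(p-1, q-1)`` and
``mu = L(g^lambda mod N^2)^{-1} mod N``.

Two encryption accelerations are provided:

* a :class:`ZeroCache` of precomputed encryptions of zero (values
  ``r^N mod N^2``); a fresh encryption multiplies ``g^m`` by a re-randomized
  cache element instead of computing a new ``N``-th power, and
* a :class:`GeneratorPowerTable` of ``g^(2^i) mod N^2`` so that ``g^m`` is a
  product of table entries selected by the bits of ``m`` (no exponentiation
  at encryption time).  With the default generator ``g = N + 1`` the closed
  form ``g^m = 1 + m*N mod N^2`` is used instead and no table is needed.

Decryption holds the prime factors and uses the standard CRT split (one
half-size exponentiation modulo ``p^2`` and one modulo ``q^2``), which is
exactly equivalent to the textbook formula; the textbook path is retained as
:func:`decrypt_textbook`.
"""

from __future__ import annotations

import hashlib
import json
import math
import secrets
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Optional, Sequence

__all__ = [
    "PaillierError",
    "KeyConfigError",
    "MissingPrivateKeyError",
    "PublicKey",
    "PrivateKey",
    "KeyPair",
    "Ciphertext",
    "ZeroCache",
    "GeneratorPowerTable",
    "keygen",
    "keypair_from_primes",
    "L",
    "encrypt",
    "encrypt_textbook",
    "decrypt",
    "decrypt_textbook",
    "hom_add",
    "hom_scalar_mult",
    "hom_add_plaintext",
    "is_probable_prime",
    "generate_prime",
]

MIN_SECURE_KEY_BITS = 1024

#: first primes, used to reject obvious composites before Miller-Rabin
_SMALL_PRIMES: tuple[int, ...] = tuple(
    n for n in range(2, 1000) if all(n % d for d in range(2, int(n**0.5) + 1))
)


class PaillierError(Exception):
    """Base error for the Paillier layer."""


class KeyConfigError(PaillierError):
    """Invalid key-generation or key-usage configuration."""


class MissingPrivateKeyError(PaillierError):
    """An operation requiring the private key was attempted without one."""


# ---------------------------------------------------------------------------
# primality


def is_probable_prime(n: int, rounds: int = 40, rng: Optional[Random] = None) -> bool:
    """Miller-Rabin probable-prime test with ``rounds`` random bases."""
    if n < 2:
        return False
    for sp in _SMALL_PRIMES:
        if n == sp:
            return True
        if n % sp == 0:
            return False
    d = n - 1
    s = 0
    while d % 2 == 0:
        d //= 2
        s += 1
    randbelow = rng.randrange if rng is not None else (lambda a, b: secrets.randbelow(b - a) + a)
    for _ in range(rounds):
        a = randbelow(2, n - 1)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = (x * x) % n
            if x == n - 1:
                break
        else:
            return False
    return True


def generate_prime(bits: int, rng: Optional[Random] = None, rounds: int = 40) -> int:
    """Random probable prime of exactly ``bits`` bits with the top two bits set.

    Forcing the two most significant bits guarantees the product of two such
    primes has exactly ``2*bits`` bits.
    """
    if bits < 3:
        raise KeyConfigError(f"cannot generate a {bits}-bit prime")
    getrandbits = rng.getrandbits if rng is not None else secrets.randbits
    while True:
        cand = getrandbits(bits) | (0b11 << (bits - 2)) | 1
        if is_probable_prime(cand, rounds=rounds, rng=rng):
            return cand


# ---------------------------------------------------------------------------
# key material


@dataclass(frozen=True)
class PublicKey:
    """Paillier public key ``(N, g)``."""

    N: int
    g: int
    key_bits: int

    def __post_init__(self) -> None:
        if self.N.bit_length() != self.key_bits:
            raise KeyConfigError(
                f"N has {self.N.bit_length()} bits, expected {self.key_bits}"
            )
        if math.gcd(self.g, self.N * self.N) != 1:
            raise KeyConfigError("generator g is not a unit modulo N^2")

    @property
    def N2(self) -> int:
        return self.N * self.N

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256(f"{self.N:x}:{self.g:x}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class PrivateKey:
    """Paillier private key ``(lambda, mu)``, plus the prime factors for CRT."""

    lam: int
    mu: int
    p: Optional[int] = None
    q: Optional[int] = None


@dataclass(frozen=True)
class Ciphertext:
    """An integer modulo ``N^2``, optionally tagged with a slot layout."""

    value: int
    layout: Optional[object] = None  # packing.SlotLayout when packed

    def with_layout(self, layout) -> "Ciphertext":
        return Ciphertext(self.value, layout)

    def to_hex(self) -> str:
        return format(self.value, "x")

    @classmethod
    def from_hex(cls, s: str, layout=None) -> "Ciphertext":
        return cls(int(s, 16), layout)


class ZeroCache:
    """Pool of precomputed encryptions of zero (values ``r^N mod N^2``).

    ``fresh()`` returns a new encryption of zero as the product of two
    distinct pool members, i.e. ``(r_i * r_j)^N mod N^2`` -- still an ``N``-th
    residue, hence still a zero -- without any exponentiation.  The product
    also replaces one of the two pool slots, so the pool re-randomizes itself
    on every draw and returned zeros do not repeat; every ``refresh_every``
    draws the whole pool is additionally stirred.
    """

    def __init__(
        self,
        pk: PublicKey,
        size: int = 64,
        rng: Optional[Random] = None,
        refresh_every: int = 1024,
    ) -> None:
        if size < 2:
            raise KeyConfigError("zero cache needs at least 2 pool members")
        self.pk = pk
        self.rng = rng
        self.refresh_every = refresh_every
        self._draws = 0
        N, N2 = pk.N, pk.N2
        pool = []
        while len(pool) < size:
            r = self._randbelow(N - 1) + 1
            if math.gcd(r, N) != 1:
                continue
            pool.append(pow(r, N, N2))
        self.pool = pool

    def _randbelow(self, n: int) -> int:
        if self.rng is not None:
            return self.rng.randrange(n)
        return secrets.randbelow(n)

    def fresh(self) -> int:
        """A new random encryption of zero, by pool re-randomization."""
        n2 = self.pk.N2
        i = self._randbelow(len(self.pool))
        j = self._randbelow(len(self.pool) - 1)
        if j >= i:
            j += 1
        v = (self.pool[i] * self.pool[j]) % n2
        self.pool[i] = v
        self._draws += 1
        if self._draws % self.refresh_every == 0:
            shift = self._randbelow(len(self.pool) - 1) + 1
            self.pool = [(a * b) % n2
                         for a, b in zip(self.pool,
                                         self.pool[shift:] + self.pool[:shift])]
        return v


class GeneratorPowerTable:
    """Precomputed ``g^(2^i) mod N^2`` for ``0 <= i < key_bits``.

    ``pow_g(m)`` multiplies the entries selected by the bits of ``m``,
    replacing the exponentiation ``g^m`` by at most ``key_bits``
    multiplications.
    """

    def __init__(self, pk: PublicKey) -> None:
        self.pk = pk
        N2 = pk.N2
        powers = [pk.g % N2]
        for _ in range(pk.key_bits - 1):
            powers.append((powers[-1] * powers[-1]) % N2)
        self.powers = powers

    def pow_g(self, m: int) -> int:
        if m < 0:
            raise ValueError("exponent must be non-negative")
        N2 = self.pk.N2
        acc = 1
        i = 0
        while m:
            if m & 1:
                acc = (acc * self.powers[i]) % N2
            m >>= 1
            i += 1
        return acc


@dataclass
class KeyPair:
    """Public key plus optional private half and acceleration tables.

    A server-side copy is obtained with :meth:`public_only` and never carries
    private components.
    """

    public: PublicKey
    private: Optional[PrivateKey] = None
    zero_cache: Optional[ZeroCache] = None
    power_table: Optional[GeneratorPowerTable] = None
    seeded: bool = False

    @property
    def has_private(self) -> bool:
        return self.private is not None

    def public_only(self) -> "KeyPair":
        return KeyPair(
            public=self.public,
            private=None,
            zero_cache=self.zero_cache,
            power_table=self.power_table,
            seeded=self.seeded,
        )

    # convenience wrappers -------------------------------------------------
    def encrypt(self, m: int) -> Ciphertext:
        return encrypt(m, self.public, zero_cache=self.zero_cache,
                       power_table=self.power_table)

    def decrypt(self, c: Ciphertext) -> int:
        return decrypt(c, self)


# ---------------------------------------------------------------------------
# scheme operations


def L(x: int, N: int) -> int:
    """The Paillier ``L`` function, ``L(x) = (x - 1) / N`` (exact division).

    ``x`` must be congruent to 1 modulo ``N``; anything else signals a
    corrupted ciphertext or a mismatched key.
    """
    if (x - 1) % N != 0:
        raise PaillierError("L(x): x is not congruent to 1 mod N "
                            "(corrupted ciphertext or wrong key)")
    return (x - 1) // N


def keypair_from_primes(
    p: int,
    q: int,
    g: Optional[int] = None,
    *,
    insecure_toy_mode: bool = False,
    rng: Optional[Random] = None,
    zero_cache_size: int = 64,
    build_power_table: bool = False,
) -> KeyPair:
    """Assemble a key pair from explicit primes (used for toy keys in tests)."""
    if p == q:
        raise KeyConfigError("p and q must differ")
    N = p * q
    key_bits = N.bit_length()
    if key_bits < MIN_SECURE_KEY_BITS and not insecure_toy_mode:
        raise KeyConfigError(
            f"{key_bits}-bit keys are insecure; pass insecure_toy_mode=True "
            "for test-only toy keys"
        )
    if g is None:
        g = N + 1
    pk = PublicKey(N=N, g=g, key_bits=key_bits)
    lam = math.lcm(p - 1, q - 1)
    denom = L(pow(g, lam, pk.N2), N)
    try:
        mu = pow(denom, -1, N)
    except ValueError as exc:  # not invertible
        raise KeyConfigError("invalid generator: L(g^lambda) not invertible mod N") from exc
    sk = PrivateKey(lam=lam, mu=mu, p=p, q=q)
    zc = ZeroCache(pk, size=zero_cache_size, rng=rng) if zero_cache_size else None
    pt = GeneratorPowerTable(pk) if (build_power_table or g != N + 1) else None
    return KeyPair(public=pk, private=sk, zero_cache=zc, power_table=pt,
                   seeded=rng is not None)


def keygen(
    key_bits: int,
    *,
    rng: Optional[Random] = None,
    g: Optional[int] = None,
    insecure_toy_mode: bool = False,
    zero_cache_size: int = 64,
    build_power_table: bool = False,
) -> KeyPair:
    """Generate a Paillier key pair with ``N`` of exactly ``key_bits`` bits.

    ``rng`` injects a deterministic generator for reproducible runs; when it
    is None all randomness comes from the operating system (``secrets``).
    Key sizes below 1024 bits are refused unless ``insecure_toy_mode`` is
    set.  The smallest slot-packing layout needs ``key_bits >= slot_bits``;
    sizes below 16 bits cannot host any packing slot of practical width and
    are rejected outright.
    """
    if key_bits < 16:
        raise KeyConfigError("key_bits too small to host any packing slot")
    if key_bits % 2 != 0:
        raise KeyConfigError("key_bits must be even")
    if key_bits < MIN_SECURE_KEY_BITS and not insecure_toy_mode:
        raise KeyConfigError(
            f"{key_bits}-bit keys are insecure; pass insecure_toy_mode=True "
            "for test-only toy keys"
        )
    half = key_bits // 2
    while True:
        p = generate_prime(half, rng=rng)
        q = generate_prime(half, rng=rng)
        if p == q:
            continue
        N = p * q
        if N.bit_length() == key_bits:
            break
    return keypair_from_primes(
        p, q, g,
        insecure_toy_mode=insecure_toy_mode,
        rng=rng,
        zero_cache_size=zero_cache_size,
        build_power_table=build_power_table,
    )


def _pow_g(m: int, pk: PublicKey, power_table: Optional[GeneratorPowerTable]) -> int:
    """``g^m mod N^2`` via closed form (g = N+1), power table, or pow()."""
    if pk.g == pk.N + 1:
        return (1 + m * pk.N) % pk.N2
    if power_table is not None:
        return power_table.pow_g(m)
    return pow(pk.g, m, pk.N2)


def encrypt(
    m: int,
    pk: PublicKey,
    *,
    zero_cache: Optional[ZeroCache] = None,
    power_table: Optional[GeneratorPowerTable] = None,
    rng: Optional[Random] = None,
) -> Ciphertext:
    """Encrypt ``m`` in ``[0, N)``; fresh randomness via the zero cache when given."""
    if not 0 <= m < pk.N:
        raise ValueError(f"plaintext out of range [0, N): {m}")
    gm = _pow_g(m, pk, power_table)
    if zero_cache is not None:
        rand = zero_cache.fresh()
    else:
        N = pk.N
        while True:
            r = (rng.randrange(N - 1) if rng is not None else secrets.randbelow(N - 1)) + 1
            if math.gcd(r, N) == 1:
                break
        rand = pow(r, N, pk.N2)
    return Ciphertext((gm * rand) % pk.N2)


def encrypt_textbook(m: int, r: int, pk: PublicKey) -> Ciphertext:
    """The unaccelerated formula ``g^m * r^N mod N^2`` (reference path)."""
    if not 0 <= m < pk.N:
        raise ValueError(f"plaintext out of range [0, N): {m}")
    if math.gcd(r, pk.N) != 1:
        raise ValueError("randomizer r must be coprime to N")
    return Ciphertext((pow(pk.g, m, pk.N2) * pow(r, pk.N, pk.N2)) % pk.N2)


def decrypt_textbook(c: Ciphertext, kp: KeyPair) -> int:
    """Textbook decryption ``L(c^lambda mod N^2) * mu mod N``."""
    if kp.private is None:
        raise MissingPrivateKeyError("decryption requires the private key")
    pk, sk = kp.public, kp.private
    return (L(pow(c.value, sk.lam, pk.N2), pk.N) * sk.mu) % pk.N


def _crt_decrypt(c: int, pk: PublicKey, sk: PrivateKey) -> int:
    p, q = sk.p, sk.q
    p2, q2 = p * p, q * q

    def half(prime: int, prime2: int) -> int:
        def Lp(x: int) -> int:
            return (x - 1) // prime
        hp = pow(Lp(pow(pk.g, prime - 1, prime2)), -1, prime)
        return (Lp(pow(c % prime2, prime - 1, prime2)) * hp) % prime

    mp, mq = half(p, p2), half(q, q2)
    # CRT combine
    u = ((mq - mp) * pow(p, -1, q)) % q
    return mp + p * u


def decrypt(c: Ciphertext, kp: KeyPair) -> int:
    """Decrypt to the plaintext in ``[0, N)`` (CRT path when factors are held)."""
    if kp.private is None:
        raise MissingPrivateKeyError("decryption requires the private key")
    sk = kp.private
    if sk.p is not None and sk.q is not None:
        return _crt_decrypt(c.value, kp.public, sk)
    return decrypt_textbook(c, kp)


def _check_same_key(c: Ciphertext, pk: PublicKey) -> None:
    if not 0 <= c.value < pk.N2:
        raise ValueError("ciphertext out of range for this key (key mismatch?)")


def _merge_layouts(l1, l2):
    if l1 is not None and l2 is not None and l1 != l2:
        raise ValueError("incompatible slot layouts")
    return l1 if l1 is not None else l2


def hom_add(c1: Ciphertext, c2: Ciphertext, pk: PublicKey) -> Ciphertext:
    """Ciphertext of ``(m1 + m2) mod N``: multiplication modulo ``N^2``."""
    _check_same_key(c1, pk)
    _check_same_key(c2, pk)
    return Ciphertext((c1.value * c2.value) % pk.N2,
                      _merge_layouts(c1.layout, c2.layout))


def hom_scalar_mult(c: Ciphertext, k: int, pk: PublicKey) -> Ciphertext:
    """Ciphertext of ``(k * m) mod N`` for a plaintext scalar ``k >= 0``.

    Shift-and-add over the bits of ``k`` (a binary multiplier built from
    homomorphic additions); equivalent to ``c^k mod N^2``.
    """
    if k < 0:
        raise ValueError("negative scalars are not representable (no negative encoding)")
    _check_same_key(c, pk)
    N2 = pk.N2
    if k == 0:
        return Ciphertext(1, c.layout)  # g^0 * 1^N: a (deterministic) zero
    acc = None
    base = c.value
    while k:
        if k & 1:
            acc = base if acc is None else (acc * base) % N2
        k >>= 1
        if k:
            base = (base * base) % N2
    return Ciphertext(acc, c.layout)


def hom_add_plaintext(
    c: Ciphertext,
    m2: int,
    pk: PublicKey,
    power_table: Optional[GeneratorPowerTable] = None,
) -> Ciphertext:
    """Ciphertext of ``(m + m2) mod N`` via ``c * g^{m2} mod N^2``."""
    if not 0 <= m2 < pk.N:
        raise ValueError(f"plaintext out of range [0, N): {m2}")
    _check_same_key(c, pk)
    return Ciphertext((c.value * _pow_g(m2, pk, power_table)) % pk.N2, c.layout)


# ---------------------------------------------------------------------------
# serialization (JSON, decimal-string big integers)


def save_public_key(kp: KeyPair, path: str | Path) -> None:
    doc = {"key_bits": kp.public.key_bits, "N": str(kp.public.N), "g": str(kp.public.g)}
    Path(path).write_text(json.dumps(doc, indent=1))


def save_private_key(kp: KeyPair, path: str | Path) -> None:
    if kp.private is None:
        raise MissingPrivateKeyError("key pair holds no private components")
    doc = {
        "key_bits": kp.public.key_bits,
        "N": str(kp.public.N),
        "g": str(kp.public.g),
        "lambda": str(kp.private.lam),
        "mu": str(kp.private.mu),
    }
    if kp.private.p is not None:
        doc["p"] = str(kp.private.p)
        doc["q"] = str(kp.private.q)
    p = Path(path)
    p.write_text(json.dumps(doc, indent=1))
    try:
        p.chmod(0o600)
    except OSError:
        pass


def load_keypair(
    public_path: str | Path,
    private_path: Optional[str | Path] = None,
    *,
    zero_cache_size: int = 64,
    rng: Optional[Random] = None,
) -> KeyPair:
    """Load a key pair; private half is optional (server-side loads omit it)."""
    pub = json.loads(Path(public_path).read_text())
    pk = PublicKey(N=int(pub["N"]), g=int(pub["g"]), key_bits=int(pub["key_bits"]))
    private = None
    if private_path is not None:
        pr = json.loads(Path(private_path).read_text())
        if int(pr["N"]) != pk.N:
            raise KeyConfigError("private key file does not match the public key")
        private = PrivateKey(
            lam=int(pr["lambda"]),
            mu=int(pr["mu"]),
            p=int(pr["p"]) if "p" in pr else None,
            q=int(pr["q"]) if "q" in pr else None,
        )
    zc = ZeroCache(pk, size=zero_cache_size, rng=rng) if zero_cache_size else None
    pt = GeneratorPowerTable(pk) if pk.g != pk.N + 1 else None
    return KeyPair(public=pk, private=private, zero_cache=zc, power_table=pt,
                   seeded=rng is not None)
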