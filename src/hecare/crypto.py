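"""Partially homomorphic encryption of patient records.

Two textbook public-key schemes sit behind one interface:

* **Paillier** (additive): ciphertexts live modulo n^2; multiplying two
  ciphertexts adds the underlying plaintexts, realizing
  E(m1) (+) E(m2) = E(m1 + m2 mod n).  Encryption is randomized (fresh r per
  call), so equal plaintexts encrypt to different ciphertexts.
* **Textbook RSA** (multiplicative, demonstration-grade, unpadded):
  multiplying ciphertexts multiplies plaintexts, E(m1) (x) E(m2) =
  E(m1 * m2 mod n).  Deterministic, hence vulnerable to dictionary matching —
  which the evaluation module's adversary exploits on purpose.

Real-valued features are carried through a base-10 fixed-point encoding
(mantissa mod n, decimal exponent); negatives use the upper half of the
residue ring with decode threshold n/2.  Key generation, bulk encryption and
decryption are timed in wall-clock milliseconds (key-generation time BT,
encryption time AT, decryption time CT); the numbers are reported, never
asserted against any particular hardware.

This module provides no cryptographic hardening (padding, constant-time
arithmetic, key rotation) and is not for production use.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
import time
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CryptoError",
    "SchemeMismatchError",
    "KeyMismatchError",
    "MessageSpaceError",
    "IntegrityError",
    "PaillierKeyPair",
    "RSAKeyPair",
    "EncodedNumber",
    "Ciphertext",
    "generate_keys",
    "encode",
    "decode",
    "encrypt",
    "decrypt",
    "encrypt_value",
    "decrypt_value",
    "he_add",
    "he_multiply",
    "encrypt_cohort",
    "decrypt_cohort",
    "plaintext_store",
    "save_keypair",
    "load_keypair",
]

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"
PLAINTEXT = "plaintext"

DEFAULT_PRECISION = 6  # decimal digits of fixed-point precision (10^-6)


class CryptoError(ValueError):
    """Base class for encryption-layer errors."""


class SchemeMismatchError(CryptoError):
    """Operation applied to ciphertexts of the wrong or differing schemes."""


class KeyMismatchError(CryptoError):
    """Ciphertexts combined under different keys, or decrypted with the wrong key."""


class MessageSpaceError(CryptoError):
    """Plaintext mantissa outside [0, n)."""


class IntegrityError(CryptoError):
    """Ciphertext store is missing or corrupting records."""


# --------------------------------------------------------------------------
# prime generation


_SMALL_PRIMES = [p for p in range(3, 1000) if all(p % q for q in range(2, p))]


def _is_probable_prime(n: int, rng: random.Random, rounds: int = 30) -> bool:
    if n < 2:
        return False
    for p in (2, *_SMALL_PRIMES):
        if n == p:
            return True
        if n % p == 0:
            return False
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    # fixed bases (deterministic below 3.3e24) plus seeded random rounds
    for a in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37):
        if not _miller_rabin_round(n, a, d, s):
            return False
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        if not _miller_rabin_round(n, a, d, s):
            return False
    return True


def _miller_rabin_round(n: int, a: int, d: int, s: int) -> bool:
    x = pow(a, d, n)
    if x in (1, n - 1):
        return True
    for _ in range(s - 1):
        x = x * x % n
        if x == n - 1:
            return True
    return False


def _random_prime(bits: int, rng: random.Random) -> int:
    if bits < 8:
        raise CryptoError(f"prime width {bits} too small")
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if _is_probable_prime(cand, rng):
            return cand


def _modinv(a: int, m: int) -> int:
    return pow(a, -1, m)


def _fingerprint(scheme: str, n: int) -> str:
    return hashlib.sha256(f"{scheme}:{n:x}".encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# key pairs


@dataclass(frozen=True)
class PaillierKeyPair:
    """Paillier key material with the g = n + 1 generator convention.

    n = p*q with gcd(n, (p-1)(q-1)) = 1; lam = lcm(p-1, q-1);
    mu = lam^-1 mod n (valid because g = n + 1 makes L(g^lam mod n^2) = lam).
    """

    n: int
    g: int
    lam: int
    mu: int
    key_bits: int

    scheme = ADDITIVE

    @classmethod
    def from_primes(cls, p: int, q: int) -> "PaillierKeyPair":
        if p == q:
            raise CryptoError("Paillier primes must be distinct")
        n = p * q
        if math.gcd(n, (p - 1) * (q - 1)) != 1:
            raise CryptoError("gcd(n, (p-1)(q-1)) must be 1")
        lam = math.lcm(p - 1, q - 1)
        mu = _modinv(lam, n)
        return cls(n=n, g=n + 1, lam=lam, mu=mu, key_bits=n.bit_length())

    @property
    def n_sq(self) -> int:
        return self.n * self.n

    @property
    def fingerprint(self) -> str:
        return _fingerprint(self.scheme, self.n)

    def encrypt_int(self, m: int, rng: random.Random, r: int | None = None) -> int:
        if not 0 <= m < self.n:
            raise MessageSpaceError(f"mantissa {m} outside [0, n)")
        n_sq = self.n_sq
        if r is None:
            while True:
                r = rng.randrange(1, self.n)
                if math.gcd(r, self.n) == 1:
                    break
        return pow(self.g, m, n_sq) * pow(r, self.n, n_sq) % n_sq

    def decrypt_int(self, c: int) -> int:
        if not 0 <= c < self.n_sq:
            raise MessageSpaceError("ciphertext outside [0, n^2)")
        u = pow(c, self.lam, self.n_sq)
        return (u - 1) // self.n * self.mu % self.n


@dataclass(frozen=True)
class RSAKeyPair:
    """Textbook (unpadded) RSA key material — demonstration grade only."""

    n: int
    e: int
    d: int
    key_bits: int

    scheme = MULTIPLICATIVE

    @classmethod
    def from_primes(cls, p: int, q: int, e: int = 65537) -> "RSAKeyPair":
        if p == q:
            raise CryptoError("RSA primes must be distinct")
        n = p * q
        lam = math.lcm(p - 1, q - 1)
        if math.gcd(e, lam) != 1:
            raise CryptoError(f"public exponent {e} not invertible mod lambda(n)")
        return cls(n=n, e=e, d=_modinv(e, lam), key_bits=n.bit_length())

    @property
    def fingerprint(self) -> str:
        return _fingerprint(self.scheme, self.n)

    def encrypt_int(self, m: int, rng: random.Random | None = None) -> int:
        if not 0 <= m < self.n:
            raise MessageSpaceError(f"mantissa {m} outside [0, n)")
        return pow(m, self.e, self.n)

    def decrypt_int(self, c: int) -> int:
        if not 0 <= c < self.n:
            raise MessageSpaceError("ciphertext outside [0, n)")
        return pow(c, self.d, self.n)


KeyPair = PaillierKeyPair | RSAKeyPair


def generate_keys(
    scheme: str, key_bits: int = 512, seed: int = 0
) -> tuple[KeyPair, float]:
    """Generate a seeded key pair; returns (keypair, key-generation time BT in ms).

    ``key_bits`` must be even and >= 32 (toy sizes allowed for tests; 512 is
    the default, 2048 the realistic choice).  Identical seeds give identical
    keys.
    """
    if key_bits < 32 or key_bits % 2 != 0:
        raise CryptoError("key_bits must be even and >= 32")
    rng = random.Random(seed)
    t0 = time.perf_counter()
    half = key_bits // 2
    while True:
        p = _random_prime(half, rng)
        q = _random_prime(half, rng)
        if p == q:
            continue
        try:
            if scheme == ADDITIVE:
                kp: KeyPair = PaillierKeyPair.from_primes(p, q)
            elif scheme == MULTIPLICATIVE:
                e = 65537 if key_bits > 20 else 7
                kp = RSAKeyPair.from_primes(p, q, e=e)
            else:
                raise CryptoError(f"unknown scheme {scheme!r}")
        except CryptoError:
            if scheme in (ADDITIVE, MULTIPLICATIVE):
                continue  # unlucky primes, retry
            raise
        break
    bt_ms = (time.perf_counter() - t0) * 1000.0
    return kp, bt_ms


# --------------------------------------------------------------------------
# fixed-point encoding


@dataclass(frozen=True)
class EncodedNumber:
    """Base-10 fixed-point residue: value = signed(mantissa) / 10^exponent."""

    mantissa: int
    exponent: int


def encode(x: float, key: KeyPair, precision: int = DEFAULT_PRECISION) -> EncodedNumber:
    """Encode a real number as a residue mod n at 10^-precision resolution.

    Negative values map to the upper half of the ring (n - |m|).
    """
    m = round(float(x) * 10**precision)
    if abs(m) >= key.n // 2:
        raise MessageSpaceError(f"{x} does not fit the message space at 10^-{precision}")
    return EncodedNumber(mantissa=m % key.n, exponent=precision)


def decode(enc: EncodedNumber, key: KeyPair) -> float:
    """Invert :func:`encode`; residues above n/2 decode as negatives."""
    m = enc.mantissa
    if m > key.n // 2:
        m -= key.n
    return m / 10**enc.exponent


# --------------------------------------------------------------------------
# ciphertexts


@dataclass(frozen=True)
class Ciphertext:
    value: int
    scheme: str
    key_fingerprint: str
    encoding_exponent: int


def encrypt(
    enc: EncodedNumber,
    key: KeyPair,
    rng: random.Random | None = None,
    r: int | None = None,
) -> Ciphertext:
    """Encrypt an encoded number under the given key's scheme.

    Paillier draws a fresh random r (pass ``r`` explicitly only in tests);
    RSA is deterministic.
    """
    if isinstance(key, PaillierKeyPair):
        value = key.encrypt_int(enc.mantissa, rng or random.Random(), r=r)
    else:
        value = key.encrypt_int(enc.mantissa)
    return Ciphertext(
        value=value,
        scheme=key.scheme,
        key_fingerprint=key.fingerprint,
        encoding_exponent=enc.exponent,
    )


def decrypt(ct: Ciphertext, key: KeyPair) -> EncodedNumber:
    if ct.key_fingerprint != key.fingerprint:
        raise KeyMismatchError("ciphertext was produced under a different key")
    if ct.scheme != key.scheme:
        raise SchemeMismatchError(f"{ct.scheme} ciphertext with {key.scheme} key")
    return EncodedNumber(mantissa=key.decrypt_int(ct.value), exponent=ct.encoding_exponent)


def encrypt_value(
    x: float,
    key: KeyPair,
    precision: int = DEFAULT_PRECISION,
    rng: random.Random | None = None,
) -> Ciphertext:
    return encrypt(encode(x, key, precision), key, rng=rng)


def decrypt_value(ct: Ciphertext, key: KeyPair) -> float:
    return decode(decrypt(ct, key), key)


def _check_pair(c1: Ciphertext, c2: Ciphertext, scheme: str) -> None:
    if c1.scheme != scheme or c2.scheme != scheme:
        raise SchemeMismatchError(
            f"expected two {scheme} ciphertexts, got {c1.scheme}/{c2.scheme}"
        )
    if c1.key_fingerprint != c2.key_fingerprint:
        raise KeyMismatchError("ciphertexts produced under different keys")


def he_add(c1: Ciphertext, c2: Ciphertext, key: PaillierKeyPair) -> Ciphertext:
    """Homomorphic addition: E(m1) * E(m2) mod n^2 decrypts to m1 + m2 mod n."""
    _check_pair(c1, c2, ADDITIVE)
    if c1.encoding_exponent != c2.encoding_exponent:
        raise CryptoError("additive operands must share an encoding exponent")
    return Ciphertext(
        value=c1.value * c2.value % key.n_sq,
        scheme=ADDITIVE,
        key_fingerprint=c1.key_fingerprint,
        encoding_exponent=c1.encoding_exponent,
    )


def he_multiply(c1: Ciphertext, c2: Ciphertext, key: RSAKeyPair) -> Ciphertext:
    """Homomorphic multiplication: E(m1) * E(m2) mod n decrypts to m1 * m2 mod n."""
    _check_pair(c1, c2, MULTIPLICATIVE)
    return Ciphertext(
        value=c1.value * c2.value % key.n,
        scheme=MULTIPLICATIVE,
        key_fingerprint=c1.key_fingerprint,
        encoding_exponent=c1.encoding_exponent + c2.encoding_exponent,
    )


# --------------------------------------------------------------------------
# cohort stores

STORE_FORMAT_VERSION = 1


def encrypt_cohort(
    records,
    key: KeyPair,
    precision: int = DEFAULT_PRECISION,
    seed: int = 0,
) -> tuple[dict, float]:
    """Encrypt every feature of every record; returns (store, encryption time AT ms).

    The store is a JSON-serializable document: scheme, key fingerprint,
    encoding exponent and per-record ciphertext values as decimal strings.
    Labels stay in the clear (the training side needs them; the adversary
    model targets feature vectors).
    """
    rng = random.Random(seed)
    t0 = time.perf_counter()
    entries = []
    for rec in records:
        values = [
            str(encrypt(encode(float(v), key, precision), key, rng=rng).value)
            for v in rec.features
        ]
        entries.append(
            {"patient_id": rec.patient_id, "label": int(rec.label), "features": values}
        )
    at_ms = (time.perf_counter() - t0) * 1000.0
    store = {
        "format_version": STORE_FORMAT_VERSION,
        "scheme": key.scheme,
        "key_fingerprint": key.fingerprint,
        "encoding_exponent": precision,
        "records": entries,
    }
    return store, at_ms


def decrypt_cohort(store: dict, key: KeyPair) -> tuple[list, float]:
    """Invert :func:`encrypt_cohort`; returns (records, decryption time CT ms)."""
    from .synth import PatientRecord  # local import to avoid a cycle

    if store.get("scheme") != key.scheme:
        raise SchemeMismatchError("store scheme does not match the key")
    if store.get("key_fingerprint") != key.fingerprint:
        raise KeyMismatchError("store was encrypted under a different key")
    exponent = int(store["encoding_exponent"])
    t0 = time.perf_counter()
    records = []
    for i, entry in enumerate(store.get("records", [])):
        feats = entry.get("features")
        if feats is None or any(v is None for v in feats):
            raise IntegrityError(f"store record {i} is missing ciphertext values")
        decoded = np.array(
            [
                decode(EncodedNumber(key.decrypt_int(int(v)), exponent), key)
                for v in feats
            ]
        )
        records.append(
            PatientRecord(
                patient_id=entry["patient_id"],
                features=decoded,
                label=int(entry["label"]),
            )
        )
    ct_ms = (time.perf_counter() - t0) * 1000.0
    return records, ct_ms


def plaintext_store(records, precision: int = DEFAULT_PRECISION) -> dict:
    """An *unencrypted* store in the same shape, for adversary baselines."""
    entries = [
        {
            "patient_id": r.patient_id,
            "label": int(r.label),
            "features": [str(round(float(v) * 10**precision)) for v in r.features],
        }
        for r in records
    ]
    return {
        "format_version": STORE_FORMAT_VERSION,
        "scheme": PLAINTEXT,
        "key_fingerprint": "",
        "encoding_exponent": precision,
        "records": entries,
    }


# --------------------------------------------------------------------------
# key serialization


def save_keypair(key: KeyPair, path, include_private: bool = True) -> None:
    doc: dict = {"scheme": key.scheme, "key_bits": key.key_bits}
    if isinstance(key, PaillierKeyPair):
        doc["public"] = {"n": str(key.n), "g": str(key.g)}
        if include_private:
            doc["private"] = {"lam": str(key.lam), "mu": str(key.mu)}
    else:
        doc["public"] = {"n": str(key.n), "e": key.e}
        if include_private:
            doc["private"] = {"d": str(key.d)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_keypair(path) -> KeyPair:
    with open(path) as fh:
        doc = json.load(fh)
    pub = doc["public"]
    priv = doc.get("private")
    if doc["scheme"] == ADDITIVE:
        if priv is None:
            raise CryptoError("private Paillier material required for decryption")
        return PaillierKeyPair(
            n=int(pub["n"]),
            g=int(pub["g"]),
            lam=int(priv["lam"]),
            mu=int(priv["mu"]),
            key_bits=int(doc["key_bits"]),
        )
    if doc["scheme"] == MULTIPLICATIVE:
        if priv is None:
            raise CryptoError("private RSA material required for decryption")
        return RSAKeyPair(
            n=int(pub["n"]),
            e=int(pub["e"]),
            d=int(priv["d"]),
            key_bits=int(doc["key_bits"]),
        )
    raise CryptoError(f"unknown scheme {doc['scheme']!r}")
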