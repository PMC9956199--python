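"""Evaluation of the detection pipeline: confusion metrics, timing, security.

Confusion counts follow the AP/AN/BP/BN naming (true positives, true
negatives, false positives, false negatives; label 1 = diseased).  Derived
metrics:

    precision = AP / (AP + BP)
    accuracy  = (AP + AN) / (AP + AN + BP + BN)
    recall    = AP / (AP + BN)            (conventional, default)
    F1        = 2 precision recall / (precision + recall)

An alternative recall variant AP / (AP + AN) — true positives over true
negatives — is available behind ``literal_recall=True`` for comparison with
sources that print that formula; it is not a standard metric and is off by
default.  Undefined ratios (zero denominators) are reported as ``None`` with
a warning rather than silently coerced to 0.

Security analysis scores a ciphertext store against a concrete, seeded
known-plaintext dictionary adversary: given the public key, the store and a
bounded dictionary of candidate feature vectors, the adversary re-encrypts
every candidate and counts the records whose feature vectors it recovers
exactly.  SA = hacked / total records, security level = 100 (1 - SA) %.
Deterministic schemes (textbook RSA, plaintext stores) fall to this attack;
randomized Paillier encryption defeats it because fresh randomness makes
equal plaintexts encrypt differently.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field

from . import crypto

__all__ = [
    "EvaluationError",
    "ConfusionCounts",
    "Metrics",
    "SecurityReport",
    "EvaluationReport",
    "confusion",
    "compute_metrics",
    "security_analysis",
    "timing_report",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """AP = true positives, AN = true negatives, BP = false positives, BN = false negatives."""

    ap: int
    an: int
    bp: int
    bn: int

    def __post_init__(self) -> None:
        if min(self.ap, self.an, self.bp, self.bn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.ap + self.an + self.bp + self.bn


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count the confusion matrix of two equal-length binary label sequences."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) == 0:
        raise EvaluationError("cannot evaluate an empty label sequence")
    if len(t) != len(p):
        raise EvaluationError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    counts = {"ap": 0, "an": 0, "bp": 0, "bn": 0}
    for yt, yp in zip(t, p):
        if yt not in (0, 1) or yp not in (0, 1):
            raise EvaluationError(f"non-binary label pair ({yt!r}, {yp!r})")
        if yt == 1 and yp == 1:
            counts["ap"] += 1
        elif yt == 0 and yp == 0:
            counts["an"] += 1
        elif yt == 0 and yp == 1:
            counts["bp"] += 1
        else:
            counts["bn"] += 1
    return ConfusionCounts(**counts)


@dataclass(frozen=True)
class Metrics:
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as None")
        return None
    return num / den


def compute_metrics(counts: ConfusionCounts, literal_recall: bool = False) -> Metrics:
    """Derive accuracy/precision/recall/F1 from confusion counts.

    ``literal_recall=True`` switches recall to the AP/(AP+AN) variant (see
    module docstring); the default is the conventional AP/(AP+BN).
    """
    if counts.total == 0:
        raise EvaluationError("total count must be positive")
    accuracy = (counts.ap + counts.an) / counts.total
    precision = _ratio(counts.ap, counts.ap + counts.bp, "precision")
    if literal_recall:
        recall = _ratio(counts.ap, counts.ap + counts.an, "recall (literal variant)")
    else:
        recall = _ratio(counts.ap, counts.ap + counts.bn, "recall")
    if precision is None or recall is None or precision + recall == 0:
        if precision is not None and recall is not None:
            warnings.warn("F1 undefined (precision + recall = 0); reported as None")
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


@dataclass(frozen=True)
class SecurityReport:
    sa: float                 # hacked / total
    level_percent: float      # 100 * (1 - SA)
    n_recovered: int
    n_records: int
    dictionary_size: int
    scheme: str

    def as_dict(self) -> dict:
        return {
            "SA": self.sa,
            "level_percent": self.level_percent,
            "n_recovered": self.n_recovered,
            "n_records": self.n_records,
            "dictionary_size": self.dictionary_size,
            "scheme": self.scheme,
        }


def security_analysis(
    store: dict,
    dictionary,
    key=None,
    seed: int = 0,
) -> SecurityReport:
    """Run the dictionary adversary against a ciphertext store.

    The adversary knows the public key, the encoding exponent and a list of
    candidate plaintext feature vectors.  For each candidate it produces the
    ciphertext it *would* obtain (using its own seeded randomness where the
    scheme demands some) and marks a stored record as recovered when every
    feature ciphertext matches.  Plaintext stores are compared directly.

    SA = recovered / total; security level = 100 (1 - SA) %.
    """
    records = store.get("records", [])
    if not records:
        raise EvaluationError("cannot analyze an empty store")
    scheme = store.get("scheme")
    exponent = int(store["encoding_exponent"])
    rng = random.Random(seed)

    candidate_sigs: set[tuple] = set()
    for vec in dictionary:
        if scheme == crypto.PLAINTEXT:
            sig = tuple(str(round(float(v) * 10**exponent)) for v in vec)
        elif scheme == crypto.MULTIPLICATIVE:
            if key is None:
                raise EvaluationError("RSA store analysis requires the public key")
            sig = tuple(
                str(key.encrypt_int(crypto.encode(float(v), key, exponent).mantissa))
                for v in vec
            )
        elif scheme == crypto.ADDITIVE:
            if key is None:
                raise EvaluationError("Paillier store analysis requires the public key")
            sig = tuple(
                str(
                    key.encrypt_int(
                        crypto.encode(float(v), key, exponent).mantissa, rng
                    )
                )
                for v in vec
            )
        else:
            raise EvaluationError(f"unknown store scheme {scheme!r}")
        candidate_sigs.add(sig)

    recovered = sum(
        1 for rec in records if tuple(rec["features"]) in candidate_sigs
    )
    sa = recovered / len(records)
    return SecurityReport(
        sa=sa,
        level_percent=100.0 * (1.0 - sa),
        n_recovered=recovered,
        n_records=len(records),
        dictionary_size=len(list(dictionary)),
        scheme=scheme,
    )


def timing_report(events: dict) -> dict:
    """Turn paired (start, end) timestamps in ms into nonnegative durations.

    ``events`` maps a stage name to a (start_ms, end_ms) pair; raises on an
    unpaired event or an end time before its start.
    """
    out = {}
    for name, pair in events.items():
        try:
            start, end = pair
        except (TypeError, ValueError) as exc:
            raise EvaluationError(f"unpaired timing event {name!r}") from exc
        start, end = float(start), float(end)
        if end < start:
            raise EvaluationError(f"event {name!r} ends before it starts")
        out[name] = end - start
    return out


@dataclass
class EvaluationReport:
    """Full report: counts, derived metrics, timing triple and security score."""

    counts: ConfusionCounts
    metrics: Metrics
    timings_ms: dict = field(default_factory=dict)
    security: SecurityReport | None = None

    def as_dict(self) -> dict:
        return {
            "counts": {
                "AP": self.counts.ap,
                "AN": self.counts.an,
                "BP": self.counts.bp,
                "BN": self.counts.bn,
            },
            "metrics": self.metrics.as_dict(),
            "timings_ms": self.timings_ms,
            "security": None if self.security is None else self.security.as_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), indent=1, **kwargs)

    def format_table(self) -> str:
        lines = [
            "              predicted 1   predicted 0",
            f"  actual 1    {self.counts.ap:11d}   {self.counts.bn:11d}",
            f"  actual 0    {self.counts.bp:11d}   {self.counts.an:11d}",
            "",
        ]
        for name, val in self.metrics.as_dict().items():
            lines.append(
                f"  {name:<10} {'undefined' if val is None else f'{val:.4f}'}"
            )
        for name, val in self.timings_ms.items():
            lines.append(f"  {name:<10} {val:.2f} ms")
        if self.security is not None:
            lines.append(
                f"  security   SA={self.security.sa:.4f} "
                f"level={self.security.level_percent:.2f}%"
            )
        return "\n".join(lines)
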