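"""Two-input Boolean logic gates from cleavage-regulated transcripts.

The construction grammar follows directly from the switch semantics: with
inputs A (Csy4) and B (CasE),

* hairpins in a transcript's 5' UTR implement an AND of negated literals
  (any listed enzyme destroys the transcript);
* hairpins in the 3' ON cassette implement an OR of positive literals
  (any listed enzyme rescues the transcript from its degradation tags);
* summing two reporter transcripts, or expressing the Cse3 intermediate
  from two transcripts, implements an OR of composite terms;
* the Cse3 intermediate inverts composite terms (its CasE-resistant mutant
  hairpin Cse3* is used so the intermediate stays orthogonal to input B).

Ten of the sixteen functions need exactly one engineered transcript; the
other six (AND, NAND, XOR, XNOR and the two implications) route through
Cse3.  All sixteen are verified by simulating the four input conditions
and calling ON/OFF against one shared ~10-fold threshold band.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CircuitSpec, ModelParams, OnMotif, Transcript, steady_state
from .registry import Registry

__all__ = ["GateConstruction", "GateResult", "GATE_FUNCTIONS", "TRUTH_TABLES",
           "build_gate", "verify_gate", "enumerate_gates",
           "DEFAULT_THRESHOLD_BAND"]

#: shared gray region on the max-normalized scale: 10-fold separation,
#: symmetric about 0.1 on a log axis
DEFAULT_THRESHOLD_BAND = (10 ** -1.5, 10 ** -0.5)

INPUT_A = "Csy4"
INPUT_B = "CasE"
INTERMEDIATE = "Cse3"

GATE_FUNCTIONS = (
    "TRUE", "FALSE", "A", "B", "NOT_A", "NOT_B", "OR", "NOR",
    "A_NIMPLY_B", "B_NIMPLY_A", "AND", "NAND", "XOR", "XNOR",
    "A_IMPLY_B", "B_IMPLY_A",
)

# condition order: (no input, A only, B only, A and B)
TRUTH_TABLES: dict[str, tuple[bool, bool, bool, bool]] = {
    "TRUE": (True, True, True, True),
    "FALSE": (False, False, False, False),
    "A": (False, True, False, True),
    "B": (False, False, True, True),
    "NOT_A": (True, False, True, False),
    "NOT_B": (True, True, False, False),
    "OR": (False, True, True, True),
    "NOR": (True, False, False, False),
    "A_NIMPLY_B": (False, True, False, False),
    "B_NIMPLY_A": (False, False, True, False),
    "AND": (False, False, False, True),
    "NAND": (True, True, True, False),
    "XOR": (False, True, True, False),
    "XNOR": (True, False, False, True),
    "A_IMPLY_B": (True, False, True, True),
    "B_IMPLY_A": (True, True, False, True),
}


@dataclass
class GateConstruction:
    function_name: str
    transcripts: list[Transcript]
    inputs: tuple[str, str]
    uses_intermediate: bool
    single_transcript: bool

    def __post_init__(self):
        if self.single_transcript and (len(self.transcripts) != 1 or self.uses_intermediate):
            raise ValueError("single_transcript gates must have one transcript and no intermediate")


@dataclass
class GateResult:
    function_name: str
    raw: tuple[float, float, float, float]
    normalized: tuple[float, float, float, float]
    calls: tuple[str, str, str, str]      # "on" | "off" | "ambiguous"
    passed: bool
    margin: float                         # min fold distance to the band
    single_transcript: bool


_REPEATS = 30


def _reporter(name: str, five=(), on=None) -> Transcript:
    return Transcript(name=name, payload="EYFP", five_prime_sites=tuple(five),
                      on_motif=on)


def _cse3(name: str, registry: Registry, five=(), on=None) -> Transcript:
    return Transcript(name=name, payload=INTERMEDIATE, pest=True,
                      five_prime_sites=tuple(five), on_motif=on)


def build_gate(function_name: str, registry: Registry) -> GateConstruction:
    """Library construction for one of the 16 two-input Boolean functions."""
    if function_name not in TRUTH_TABLES:
        raise ValueError(f"unknown gate {function_name!r}; valid names: "
                         + ", ".join(GATE_FUNCTIONS))
    sa = registry.cognate_site(INPUT_A).site_id
    sb = registry.cognate_site(INPUT_B).site_id
    sc = "Cse3star-site"  # CasE-resistant mutant hairpin, read only by Cse3
    on = lambda *sites: OnMotif(sites=sites, deg_repeats=_REPEATS)  # noqa: E731

    single = {
        "TRUE": [_reporter("rep")],
        "FALSE": [_reporter("rep", on=on())],
        "A": [_reporter("rep", on=on(sa))],
        "B": [_reporter("rep", on=on(sb))],
        "NOT_A": [_reporter("rep", five=(sa,))],
        "NOT_B": [_reporter("rep", five=(sb,))],
        "OR": [_reporter("rep", on=on(sa, sb))],
        "NOR": [_reporter("rep", five=(sa, sb))],
        "A_NIMPLY_B": [_reporter("rep", five=(sb,), on=on(sa))],
        "B_NIMPLY_A": [_reporter("rep", five=(sa,), on=on(sb))],
    }
    if function_name in single:
        return GateConstruction(function_name, single[function_name],
                                (INPUT_A, INPUT_B), False, True)

    # Cse3-intermediate constructions: the intermediate computes a composite
    # term; the reporter reads it straight (ON cassette) or inverted (5').
    nand_pair = [_cse3("int1", registry, five=(sa,)),
                 _cse3("int2", registry, five=(sb,))]          # Cse3 = !A | !B
    xor_pair = [_cse3("int1", registry, five=(sb,), on=on(sa)),
                _cse3("int2", registry, five=(sa,), on=on(sb))]  # Cse3 = A xor B
    multi = {
        "AND": nand_pair + [_reporter("rep", five=(sc,))],
        "NAND": nand_pair + [_reporter("rep", on=on(sc))],
        "XOR": xor_pair + [_reporter("rep", on=on(sc))],
        "XNOR": xor_pair + [_reporter("rep", five=(sc,))],
        "A_IMPLY_B": [_cse3("int1", registry, five=(sb,), on=on(sa)),
                      _reporter("rep", five=(sc,))],          # !(A & !B)
        "B_IMPLY_A": [_cse3("int1", registry, five=(sa,), on=on(sb)),
                      _reporter("rep", five=(sc,))],          # !(B & !A)
    }
    return GateConstruction(function_name, multi[function_name],
                            (INPUT_A, INPUT_B), True, False)


# low intermediate dosing keeps the degraded-intermediate leak from
# dragging ON conditions into the gray band while an activated intermediate
# still represses the reporter several-hundred-fold
_COPIES = {"rep": 100.0, "int1": 3.0, "int2": 3.0}
_INPUT_COPIES = 300.0


def _simulate_conditions(g: GateConstruction, registry: Registry,
                         params: ModelParams) -> tuple[list[float], float]:
    """Raw EYFP output under (no input, A, B, AB) + constitutive reference."""
    a_t = Transcript(name="inputA", payload=INPUT_A)
    b_t = Transcript(name="inputB", payload=INPUT_B)
    raw = []
    for a_on, b_on in ((False, False), (True, False), (False, True), (True, True)):
        copies = {t.name: _COPIES[t.name] for t in g.transcripts}
        copies["inputA"] = _INPUT_COPIES if a_on else 0.0
        copies["inputB"] = _INPUT_COPIES if b_on else 0.0
        spec = CircuitSpec(g.transcripts + [a_t, b_t], copies, registry)
        raw.append(steady_state(spec, params).proteins["EYFP"])
    ref_spec = CircuitSpec([_reporter("rep")], {"rep": _COPIES["rep"]}, registry)
    reference = steady_state(ref_spec, params).proteins["EYFP"]
    return raw, reference


def call_outputs(raw, band, reference: float | None = None):
    """Normalize four-condition outputs and call each against the band.

    Outputs are scaled by the larger of their own maximum and the
    constitutive reference level, so a gate whose four conditions are all
    dim (e.g. FALSE) is judged on the absolute scale rather than having its
    noise floor promoted to 1.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("threshold band must satisfy lo < hi")
    denom = max(raw)
    if reference is not None:
        denom = max(denom, reference)
    norm = tuple(min(r / denom, 1.0) for r in raw)
    calls = tuple("on" if v > hi else "off" if v < lo else "ambiguous" for v in norm)
    margins = [v / hi if c == "on" else lo / v if (c == "off" and v > 0) else
               (float("inf") if c == "off" else 1.0) for v, c in zip(norm, calls)]
    return norm, calls, min(margins)


def verify_gate(g: GateConstruction, params: ModelParams,
                threshold_band=DEFAULT_THRESHOLD_BAND,
                registry: Registry | None = None) -> GateResult:
    """Simulate the four input conditions and check the truth table."""
    if registry is None:
        from .registry import default_registry
        registry = default_registry()
    raw, reference = _simulate_conditions(g, registry, params)
    norm, calls, margin = call_outputs(raw, threshold_band, reference)
    expected = TRUTH_TABLES[g.function_name]
    passed = all(c == ("on" if e else "off") for c, e in zip(calls, expected))
    return GateResult(g.function_name, tuple(raw), norm, calls, passed,
                      margin, g.single_transcript)


def enumerate_gates(registry: Registry, params: ModelParams,
                    threshold_band=DEFAULT_THRESHOLD_BAND):
    """Verify all 16 functions; returns (DataFrame, n_pass, n_single)."""
    import pandas as pd

    rows = []
    for name in GATE_FUNCTIONS:
        g = build_gate(name, registry)
        r = verify_gate(g, params, threshold_band, registry)
        rows.append({"function": name, "passed": r.passed,
                     "single_transcript": r.single_transcript,
                     "margin": r.margin,
                     **{f"raw_{c}": v for c, v in zip("0ABX", r.raw)},
                     **{f"norm_{c}": v for c, v in zip("0ABX", r.normalized)},
                     **{f"call_{c}": v for c, v in zip("0ABX", r.calls)}})
    df = pd.DataFrame(rows)
    return df, int(df["passed"].sum()), int(df["single_transcript"].sum())
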