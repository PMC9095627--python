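"""Builders for the standard circuit motifs.

Every construction follows the same grammar: a hairpin in a transcript's
5' UTR makes the cognate enzyme a repressor of that transcript; a hairpin
inside the 3' ON cassette (stabilizer - site - degradation repeats) makes
the enzyme an activator.  Enzymes placed downstream of another enzyme carry
a PEST tag for faster switching.
"""

from __future__ import annotations

from .model import CircuitSpec, OnMotif, Transcript
from .registry import Registry

DEFAULT_REPEATS = 30


def plain_reporter(registry: Registry, payload: str = "EYFP",
                   copies: float = 100.0) -> CircuitSpec:
    t = Transcript(name="reporter", payload=payload)
    return CircuitSpec([t], {"reporter": copies}, registry)


def off_reporter(registry: Registry, enzyme: str, payload: str = "EYFP",
                 copies: float = 100.0, enzyme_copies: float = 0.0,
                 site: str | None = None) -> CircuitSpec:
    """Reporter with the enzyme's hairpin in its 5' UTR + the enzyme itself."""
    sid = site or registry.cognate_site(enzyme).site_id
    rep = Transcript(name="reporter", payload=payload, five_prime_sites=(sid,))
    enz = Transcript(name="enzyme", payload=enzyme)
    return CircuitSpec([rep, enz], {"reporter": copies, "enzyme": enzyme_copies},
                       registry)


def on_reporter(registry: Registry, enzyme: str, payload: str = "EYFP",
                copies: float = 100.0, enzyme_copies: float = 0.0,
                deg_repeats: int = DEFAULT_REPEATS,
                rnasep_site: bool = False) -> CircuitSpec:
    """Reporter whose ON cassette carries the enzyme's hairpin."""
    sid = registry.cognate_site(enzyme).site_id
    rep = Transcript(name="reporter", payload=payload,
                     on_motif=OnMotif(sites=(sid,), deg_repeats=deg_repeats,
                                      rnasep_site=rnasep_site))
    enz = Transcript(name="enzyme", payload=enzyme)
    return CircuitSpec([rep, enz], {"reporter": copies, "enzyme": enzyme_copies},
                       registry)


def degraded_reporter(registry: Registry, deg_repeats: int,
                      payload: str = "EYFP", copies: float = 100.0,
                      rnasep_site: bool = False) -> CircuitSpec:
    """Reporter with degradation repeats but no enzyme hairpin (ladder arm)."""
    rep = Transcript(name="reporter", payload=payload,
                     on_motif=OnMotif(sites=(), deg_repeats=deg_repeats,
                                      rnasep_site=rnasep_site))
    return CircuitSpec([rep], {"reporter": copies}, registry)


def repression_cascade(registry: Registry, upstream: str = "CasE",
                       intermediate: str = "Csy4",
                       reporter_copies: float = 100.0,
                       intermediate_copies: float = 25.0,
                       upstream_copies: float = 0.0) -> CircuitSpec:
    """Two-stage repression: upstream represses intermediate represses reporter."""
    up_site = registry.cognate_site(upstream).site_id
    mid_site = registry.cognate_site(intermediate).site_id
    rep = Transcript(name="reporter", payload="EYFP", five_prime_sites=(mid_site,))
    mid = Transcript(name="intermediate", payload=intermediate,
                     five_prime_sites=(up_site,), pest=True)
    up = Transcript(name="input", payload=upstream)
    return CircuitSpec([rep, mid, up],
                       {"reporter": reporter_copies,
                        "intermediate": intermediate_copies,
                        "input": upstream_copies}, registry)


def activation_cascade(registry: Registry, upstream: str = "CasE",
                       intermediate: str = "Csy4",
                       reporter_copies: float = 100.0,
                       intermediate_copies: float = 25.0,
                       upstream_copies: float = 0.0,
                       deg_repeats: int = DEFAULT_REPEATS) -> CircuitSpec:
    """Upstream activates intermediate (ON motif) which represses the reporter."""
    up_site = registry.cognate_site(upstream).site_id
    mid_site = registry.cognate_site(intermediate).site_id
    rep = Transcript(name="reporter", payload="EYFP", five_prime_sites=(mid_site,))
    mid = Transcript(name="intermediate", payload=intermediate, pest=True,
                     on_motif=OnMotif(sites=(up_site,), deg_repeats=deg_repeats))
    up = Transcript(name="input", payload=upstream)
    return CircuitSpec([rep, mid, up],
                       {"reporter": reporter_copies,
                        "intermediate": intermediate_copies,
                        "input": upstream_copies}, registry)


def auto_positive_feedback(registry: Registry, enzyme: str = "CasE",
                           copies: float = 100.0, with_site: bool = True,
                           deg_repeats: int = DEFAULT_REPEATS) -> CircuitSpec:
    """Enzyme with (or without) its own hairpin in its ON cassette."""
    sid = (registry.cognate_site(enzyme).site_id,) if with_site else ()
    t = Transcript(name="auto", payload=enzyme,
                   on_motif=OnMotif(sites=sid, deg_repeats=deg_repeats))
    return CircuitSpec([t], {"auto": copies}, registry)


def cffl(registry: Registry, input_enzyme: str = "CasE",
         intermediate: str = "Csy4", reporter_copies: float = 100.0,
         intermediate_copies: float = 20.0, input_copies: float = 0.0,
         deg_repeats: int = DEFAULT_REPEATS) -> CircuitSpec:
    """Coherent feed-forward loop with a dual-function input enzyme.

    The input activates the reporter through its ON cassette and represses
    the intermediate, which represses the reporter through its 5' hairpin —
    both paths push the reporter the same way, lowering the background and
    widening the dynamic range.
    """
    in_site = registry.cognate_site(input_enzyme).site_id
    mid_site = registry.cognate_site(intermediate).site_id
    rep = Transcript(name="reporter", payload="EYFP",
                     five_prime_sites=(mid_site,),
                     on_motif=OnMotif(sites=(in_site,), deg_repeats=deg_repeats))
    mid = Transcript(name="intermediate", payload=intermediate,
                     five_prime_sites=(in_site,), pest=True)
    inp = Transcript(name="input", payload=input_enzyme)
    return CircuitSpec([rep, mid, inp],
                       {"reporter": reporter_copies,
                        "intermediate": intermediate_copies,
                        "input": input_copies}, registry)


def toggle(registry: Registry, enzymes: tuple[str, str] = ("Csy4", "Cse3"),
           reporters: tuple[str, str] = ("EYFP", "mKO2"),
           node_copies: tuple[float, float] = (60.0, 60.0),
           reporter_copies: tuple[float, float] = (60.0, 60.0),
           deg_repeats: int = DEFAULT_REPEATS,
           self_activation: bool = True) -> CircuitSpec:
    """Two-node bistable switch: cross-repression plus self ON-activation.

    Node A (enzyme ``enzymes[0]``) carries node B's hairpin in its 5' UTR
    and its own hairpin in its ON cassette, and vice versa.  Each node's
    reporter carries the *opposing* enzyme's 5' hairpin, so the reporter is
    bright in the state where its own node has won.
    """
    a, b = enzymes
    ra, rb = reporters
    sa = registry.cognate_site(a).site_id
    # the Cse3 node uses the CasE-resistant mutant hairpin so only Cse3 reads it
    sb = ("Cse3star-site" if b == "Cse3" and
          any(s.site_id == "Cse3star-site" for s in registry.sites)
          else registry.cognate_site(b).site_id)
    on_a = OnMotif(sites=(sa,), deg_repeats=deg_repeats) if self_activation else None
    on_b = OnMotif(sites=(sb,), deg_repeats=deg_repeats) if self_activation else None
    node_a = Transcript(name="nodeA", payload=a, five_prime_sites=(sb,),
                        on_motif=on_a, pest=True)
    node_b = Transcript(name="nodeB", payload=b, five_prime_sites=(sa,),
                        on_motif=on_b, pest=True)
    rep_a = Transcript(name="reporterA", payload=ra, five_prime_sites=(sb,))
    rep_b = Transcript(name="reporterB", payload=rb, five_prime_sites=(sa,))
    return CircuitSpec(
        [node_a, node_b, rep_a, rep_b],
        {"nodeA": node_copies[0], "nodeB": node_copies[1],
         "reporterA": reporter_copies[0], "reporterB": reporter_copies[1]},
        registry)
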