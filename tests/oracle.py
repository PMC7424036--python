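"""Naive reference implementation of the pair screen, for oracle tests.

Deliberately independent of the package internals: double loop over cases
per pair, textbook formulas, no shared helpers beyond the data classes.
"""

import math


def naive_table(cases, drug, event):
    a = b = c = d = 0
    for case in cases:
        has_d = drug in {x.drug_name for x in case.drugs}
        has_e = event in {x.event_term for x in case.events}
        if has_d and has_e:
            a += 1
        elif has_d and not has_e:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return a, b, c, d


def naive_screen(cases, monitoring, ime, min_a=3):
    """All pairs with a >= min_a: {(drug, event): (a,b,c,d,ror,lo,sentinel,is_sdr)}."""
    drugs = sorted({x.drug_name for case in cases for x in case.drugs})
    events = sorted({x.event_term for case in cases for x in case.events})
    out = {}
    for drug in drugs:
        for event in events:
            a, b, c, d = naive_table(cases, drug, event)
            if a < min_a:
                continue
            if c == 0:
                ror, lo, sentinel = 99.9, None, True
            else:
                aa, bb, cc, dd = a, b, c, d
                if b == 0 or d == 0:
                    aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                ror = (aa * dd) / (cc * bb)
                se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
                lo = math.exp(math.log(ror) - 1.959963984540054 * se)
                sentinel = False
            count_ok = (drug in monitoring and a >= 3) or a >= 5
            is_sdr = (
                event in ime
                and count_ok
                and (sentinel or lo > 1)
            )
            out[(drug, event)] = (a, b, c, d, ror, lo, sentinel, is_sdr)
    return out


def random_fixture(rng, n_cases, drug_vocab, event_vocab):
    """A random small database of CaseReport objects."""
    from pedpv.icsr_model import CaseReport, DrugEntry, EventEntry

    cases = []
    for i in range(n_cases):
        n_d = int(rng.integers(1, 4))
        n_e = int(rng.integers(1, 4))
        drugs = rng.choice(drug_vocab, size=n_d, replace=False)
        events = rng.choice(event_vocab, size=n_e, replace=False)
        cases.append(
            CaseReport(
                case_id=f"R{i:03d}",
                seriousness="medically_important",
                age_days=int(rng.integers(0, 4000)),
                drugs=[DrugEntry(d) for d in drugs],
                events=[EventEntry(e) for e in events],
            )
        )
    return cases
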