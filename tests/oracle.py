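"""Independent scalar oracle for the 37 per-gene features.

A deliberately naive, loop-based re-derivation of every feature from a list
of plain record dicts, sharing no code with the package.  Used to pin the
vectorised feature engine down to 1e-9.
"""

import math
from collections import Counter

FEATURE_ORDER = [
    "Silent/kb", "Total Missense", "Total Splicing", "Total LOF", "Missense/kb",
    "LOF/kb", "LOF/Silent", "Splicing/Silent", "Missense/Silent", "LOF/Benign",
    "Splicing/Benign", "Missense/Benign", "average Polyphen2 score", "LOF/Total",
    "Missense/Total", "Splicing/Total", "LOF/Missense", "Missense entropy",
    "HiFI/LoFI", "HiFI/Benign", "MiFI/kb", "Nonstop/kb", "Inframe/kb",
    "Complex/kb", "Compound/Benign", "Compound/kB", "Damaging/kb",
    "Damaging/Benign", "Damaging/LoFI", "High Missense frequency",
    "Frameshift entropy", "High Frameshift frequency", "Splicing entropy",
    "High Splicing frequency", "Nonsense entropy", "High Nonsense frequency",
    "Total MiFI",
]


def categories(records):
    """Category counts for one gene from record dicts (type, score keys)."""
    c = Counter()
    for r in records:
        t = r["mutation_type"]
        c[t] += 1
        if t == "missense":
            s = r.get("impact_score")
            if s is None:
                c["MiFI"] += 1
            elif s >= 0.85:
                c["HiFI"] += 1
            elif s <= 0.15:
                c["LoFI"] += 1
            else:
                c["MiFI"] += 1
    c["LOF"] = c["nonsense"] + c["frameshift"]
    c["damaging"] = c["HiFI"] + c["MiFI"]
    c["benign"] = c["silent"] + c["LoFI"]
    c["compound"] = c["missense"] + c["complex"] + c["inframe"] + c["nonstop"] - c["LoFI"]
    c["total"] = len(records)
    return c


def ratio(a, b, max_a):
    return a / b if b != 0 else 2 * max_a


def spectrum(records, mtype):
    ids = Counter()
    for r in records:
        if r["mutation_type"] != mtype:
            continue
        if mtype == "missense":
            ids[(r["position"], r["ref_allele"], r["alt_allele"])] += 1
        else:
            ids[r["position"]] += 1
    k = len(ids)
    if k == 0:
        return 0.0, 0.0
    n = sum(ids.values())
    s = 0.0
    hf = 0.0
    for cnt in ids.values():
        f = cnt / n
        s += f * math.log(f)
        hf = max(hf, f)
    return math.log(k) - s, hf


def gene_features(records, length_bp, max_counts):
    """All 37 features for one gene; ``max_counts`` maps category -> matrix max."""
    c = categories(records)
    kb = length_bp / 1000.0
    scored = [r["impact_score"] for r in records
              if r["mutation_type"] == "missense" and r.get("impact_score") is not None]
    avg = sum(scored) / len(scored) if scored else 0.0
    mis_e, mis_f = spectrum(records, "missense")
    fs_e, fs_f = spectrum(records, "frameshift")
    sp_e, sp_f = spectrum(records, "splicing")
    ns_e, ns_f = spectrum(records, "nonsense")
    total = c["total"]
    return {
        "Silent/kb": c["silent"] / kb,
        "Total Missense": c["missense"],
        "Total Splicing": c["splicing"],
        "Total LOF": c["LOF"],
        "Missense/kb": c["missense"] / kb,
        "LOF/kb": c["LOF"] / kb,
        "LOF/Silent": ratio(c["LOF"], c["silent"], max_counts["LOF"]),
        "Splicing/Silent": ratio(c["splicing"], c["silent"], max_counts["splicing"]),
        "Missense/Silent": ratio(c["missense"], c["silent"], max_counts["missense"]),
        "LOF/Benign": ratio(c["LOF"], c["benign"], max_counts["LOF"]),
        "Splicing/Benign": ratio(c["splicing"], c["benign"], max_counts["splicing"]),
        "Missense/Benign": ratio(c["missense"], c["benign"], max_counts["missense"]),
        "average Polyphen2 score": avg,
        "LOF/Total": c["LOF"] / total,
        "Missense/Total": c["missense"] / total,
        "Splicing/Total": c["splicing"] / total,
        "LOF/Missense": ratio(c["LOF"], c["missense"], max_counts["LOF"]),
        "Missense entropy": mis_e,
        "HiFI/LoFI": ratio(c["HiFI"], c["LoFI"], max_counts["HiFI"]),
        "HiFI/Benign": ratio(c["HiFI"], c["benign"], max_counts["HiFI"]),
        "MiFI/kb": c["MiFI"] / kb,
        "Nonstop/kb": c["nonstop"] / kb,
        "Inframe/kb": c["inframe"] / kb,
        "Complex/kb": c["complex"] / kb,
        "Compound/Benign": ratio(c["compound"], c["benign"], max_counts["compound"]),
        "Compound/kB": c["compound"] / kb,
        "Damaging/kb": c["damaging"] / kb,
        "Damaging/Benign": ratio(c["damaging"], c["benign"], max_counts["damaging"]),
        "Damaging/LoFI": ratio(c["damaging"], c["LoFI"], max_counts["damaging"]),
        "High Missense frequency": mis_f,
        "Frameshift entropy": fs_e,
        "High Frameshift frequency": fs_f,
        "Splicing entropy": sp_e,
        "High Splicing frequency": sp_f,
        "Nonsense entropy": ns_e,
        "High Nonsense frequency": ns_f,
        "Total MiFI": c["MiFI"],
    }


def feature_table(records_by_gene, lengths_by_gene):
    """Features for a whole cohort of per-gene record lists."""
    max_counts = Counter()
    cats = {g: categories(rs) for g, rs in records_by_gene.items() if rs}
    for c in cats.values():
        for key in ("LOF", "splicing", "missense", "HiFI", "compound", "damaging"):
            max_counts[key] = max(max_counts[key], c[key])
    return {
        g: gene_features(records_by_gene[g], lengths_by_gene[g], max_counts)
        for g in cats
    }
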