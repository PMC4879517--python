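"""Primer picking, melting-temperature filtering, panel curation and linkers.

Primers are picked directly on the allele-consensus templates: with the
default 22-bp primer length the forward primer is the 22 bases immediately
left of the SNP and the reverse primer the reverse complement of the 22 bases
immediately right of it, so the SNP sits at the center of a 45-bp amplicon
and neither primer covers the SNP base (no allele bias by design).

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia unified
parameter set, fixed salt/strand concentrations in :data:`TM_CONFIG`).
Curation drops primers with Tm outside the 47-79 degC retention window, flags
those outside the 52-70 degC recommended window, and resolves overlapping
amplicons in favor of the smaller anchor-LD P-value.

Constant 5' linker tails (Nextera-style) let a second PCR add dual sample
indexes; the forward linker is 33 nt and the reverse linker 34 nt, so a
22-bp primer becomes a 55/56-nt linkered oligo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .io import SnpSite
from .templates import FEATURE_NAMES, AlleleTemplate, RejectCode

FORWARD_LINKER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"  # 33 nt, S5xx side
REVERSE_LINKER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"  # 34 nt, N7xx side

DEFAULT_PRIMER_LEN = 22
RETAIN_TM = (47.0, 79.0)
RECOMMEND_TM = (52.0, 70.0)

#: fixed thermodynamic conditions for the nearest-neighbor Tm
TM_CONFIG = {"Na": 50.0, "dnac1": 25.0, "dnac2": 25.0, "saltcorr": 5}


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (degC) of a primer/template
    duplex under the fixed conditions in :data:`TM_CONFIG`."""
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=TM_CONFIG["Na"],
            dnac1=TM_CONFIG["dnac1"],
            dnac2=TM_CONFIG["dnac2"],
            saltcorr=TM_CONFIG["saltcorr"],
        )
    )


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class TemplateTooShortError(ValueError):
    """Template flank shorter than the requested primer length."""


@dataclass
class PrimerPair:
    """A designed forward/reverse primer pair around one SNP."""

    template: AlleleTemplate
    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    amplicon_start: int
    amplicon_end: int
    linkered_fwd: str = ""
    linkered_rev: str = ""
    tm_flag: str = ""  # '' or 'outside_recommended'

    @property
    def site(self) -> SnpSite:
        return self.template.site

    @property
    def amplicon_len(self) -> int:
        return self.amplicon_end - self.amplicon_start + 1

    def overlaps(self, other: "PrimerPair") -> bool:
        return (
            self.site.chrom == other.site.chrom
            and self.amplicon_start <= other.amplicon_end
            and other.amplicon_start <= self.amplicon_end
        )


@dataclass
class AmpliconPanel:
    pairs: list[PrimerPair]
    trait: str = ""
    curation_log: list[tuple[str, str, str]] = field(default_factory=list)  # (marker, action, reason)


def design_primer_pair(template: AlleleTemplate, primer_len: int = DEFAULT_PRIMER_LEN) -> PrimerPair:
    """Design the SNP-centered primer pair on a design-eligible template.

    Requires reject code 0 and both allele-1 flanks at least ``primer_len``
    long; the resulting amplicon spans 2*primer_len + 1 reference bases (45
    with defaults). Tm values are written back to the template's
    ltemp/rtemp parameters.
    """
    if template.reject_code != RejectCode.OK:
        raise ValueError(
            f"template {template.site.name} has reject_code {template.reject_code}; only 0 is design-eligible"
        )
    if template.a1_lseq_len < primer_len or template.a1_rseq_len < primer_len:
        raise TemplateTooShortError(
            f"template_too_short: {template.site.name} flanks "
            f"{template.a1_lseq_len}/{template.a1_rseq_len} < primer_len {primer_len}"
        )
    fwd = template.a1_lseq[-primer_len:]
    rev = revcomp(template.a1_rseq[:primer_len])
    fwd_tm = primer_tm(fwd)
    rev_tm = primer_tm(rev)
    template.ltemp = fwd_tm
    template.rtemp = rev_tm
    pos = template.site.pos
    return PrimerPair(
        template=template,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_tm=fwd_tm,
        rev_tm=rev_tm,
        amplicon_start=pos - primer_len,
        amplicon_end=pos + primer_len,
    )


def attach_linkers(pair: PrimerPair) -> PrimerPair:
    """Prepend the constant forward/reverse linker tails to the primers."""
    pair.linkered_fwd = FORWARD_LINKER + pair.fwd_seq
    pair.linkered_rev = REVERSE_LINKER + pair.rev_seq
    return pair


def curate_panel(
    candidates: list[PrimerPair],
    retain_tm: tuple[float, float] = RETAIN_TM,
    recommend_tm: tuple[float, float] = RECOMMEND_TM,
    trait: str = "",
) -> AmpliconPanel:
    """Apply the curation rules to candidate primer pairs.

    Drops pairs with either Tm outside ``retain_tm``; flags (keeps) pairs
    outside ``recommend_tm``; among overlapping amplicons keeps the one with
    the smallest anchor-LD P-value. Every decision is recorded in the
    curation log. Idempotent.
    """
    log: list[tuple[str, str, str]] = []
    kept: list[PrimerPair] = []
    for pair in sorted(candidates, key=lambda p: (p.site.chrom, p.amplicon_start)):
        lo, hi = retain_tm
        if not (lo <= pair.fwd_tm <= hi) or not (lo <= pair.rev_tm <= hi):
            log.append((pair.site.name, "drop",
                        f"Tm {pair.fwd_tm:.1f}/{pair.rev_tm:.1f} outside retention window {lo}-{hi}"))
            continue
        rlo, rhi = recommend_tm
        if not (rlo <= pair.fwd_tm <= rhi) or not (rlo <= pair.rev_tm <= rhi):
            pair.tm_flag = "outside_recommended"
            log.append((pair.site.name, "flag",
                        f"Tm {pair.fwd_tm:.1f}/{pair.rev_tm:.1f} outside recommended window {rlo}-{rhi}"))
        elif pair.tm_flag == "outside_recommended":
            pair.tm_flag = ""

        kept.append(pair)

    # resolve clusters of transitively overlapping amplicons: keep smallest LD P
    final: list[PrimerPair] = []
    i = 0
    while i < len(kept):
        cluster = [kept[i]]
        j = i + 1
        while j < len(kept) and any(kept[j].overlaps(c) for c in cluster):
            cluster.append(kept[j])
            j += 1
        if len(cluster) > 1:
            def ld_p(p: PrimerPair) -> float:
                v = p.template.pvalue
                return v if not math.isnan(v) else float("inf")

            winner = min(cluster, key=lambda p: (ld_p(p), p.amplicon_start))
            for p in cluster:
                if p is winner:
                    log.append((p.site.name, "keep",
                                f"best anchor-LD P among {len(cluster)} overlapping amplicons"))
                else:
                    log.append((p.site.name, "drop",
                                f"overlaps {winner.site.name} with smaller anchor-LD P"))
            final.append(winner)
        else:
            final.append(cluster[0])
        i = j
    return AmpliconPanel(pairs=final, trait=trait, curation_log=log)


# ---------------------------------------------------------------------------
# Panel TSV serialization (lossless round trip of template + primer fields)
# ---------------------------------------------------------------------------

_SEQ_COLUMNS = ["a1_lseq", "a1_rseq", "a2_lseq", "a2_rseq"]
_PRIMER_COLUMNS = [
    "fwd_seq", "rev_seq", "amplicon_start", "amplicon_end",
    "linkered_fwd", "linkered_rev", "tm_flag",
]
PANEL_COLUMNS = (
    ["marker", "chrom", "pos", "ref", "alt", "trait"]
    + FEATURE_NAMES
    + _SEQ_COLUMNS
    + _PRIMER_COLUMNS
)

_LEN_COLUMNS = {"a1_lseq_len", "a1_rseq_len", "a2_lseq_len", "a2_rseq_len"}


def panel_to_frame(panel: AmpliconPanel) -> pd.DataFrame:
    rows = []
    for pair in panel.pairs:
        t = pair.template
        row: dict = {
            "marker": t.site.name,
            "chrom": t.site.chrom,
            "pos": t.site.pos,
            "ref": t.site.ref_allele,
            "alt": t.site.alt_allele,
            "trait": panel.trait,
        }
        for name in FEATURE_NAMES:
            row[name] = getattr(t, name)
        for name in _SEQ_COLUMNS:
            row[name] = getattr(t, name)
        row.update(
            fwd_seq=pair.fwd_seq,
            rev_seq=pair.rev_seq,
            amplicon_start=pair.amplicon_start,
            amplicon_end=pair.amplicon_end,
            linkered_fwd=pair.linkered_fwd,
            linkered_rev=pair.linkered_rev,
            tm_flag=pair.tm_flag,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel(panel: AmpliconPanel, path: str) -> None:
    """Write the panel as a TSV (header-only when the panel is empty)."""
    panel_to_frame(panel).to_csv(path, sep="\t", index=False, na_rep="NaN")


def read_panel(path: str) -> AmpliconPanel:
    """Read a panel TSV back; unknown columns are a hard error."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NaN"])
    unknown = [c for c in df.columns if c not in PANEL_COLUMNS]
    if unknown:
        raise ValueError(f"unknown panel column(s): {unknown}")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing column(s): {missing}")
    pairs: list[PrimerPair] = []
    trait = ""
    for _, row in df.iterrows():
        site = SnpSite(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        t = AlleleTemplate(
            site=site,
            num_tags=int(row["num_tags"]),
            pvalue=float(row["pvalue"]),
            phase=int(row["phase"]),
            reject_code=int(row["reject_code"]),
            a1=str(row["a1"]) if row["a1"] else "",
            a2=str(row["a2"]) if row["a2"] else "",
            a1_count=int(row["a1_count"]),
            a2_count=int(row["a2_count"]),
            a1_lseq=str(row["a1_lseq"]),
            a1_rseq=str(row["a1_rseq"]),
            a2_lseq=str(row["a2_lseq"]),
            a2_rseq=str(row["a2_rseq"]),
            a1_lseq_pct=float(row["a1_lseq_pct"]),
            a1_rseq_pct=float(row["a1_rseq_pct"]),
            a2_lseq_pct=float(row["a2_lseq_pct"]),
            a2_rseq_pct=float(row["a2_rseq_pct"]),
            ltemp=float(row["ltemp"]),
            rtemp=float(row["rtemp"]),
        )
        for col in _LEN_COLUMNS:
            stored = int(row[col])
            if stored != getattr(t, col):
                raise ValueError(
                    f"{site.name}: stored {col}={stored} disagrees with sequence length {getattr(t, col)}"
                )
        pairs.append(
            PrimerPair(
                template=t,
                fwd_seq=str(row["fwd_seq"]),
                rev_seq=str(row["rev_seq"]),
                fwd_tm=float(row["ltemp"]),
                rev_tm=float(row["rtemp"]),
                amplicon_start=int(row["amplicon_start"]),
                amplicon_end=int(row["amplicon_end"]),
                linkered_fwd=str(row["linkered_fwd"]),
                linkered_rev=str(row["linkered_rev"]),
                tm_flag=str(row["tm_flag"]),
            )
        )
        trait = str(row["trait"])
    return AmpliconPanel(pairs=pairs, trait=trait)


def write_primer_fasta(panel: AmpliconPanel, path: str) -> None:
    """FASTA of linkered primers for oligo ordering."""
    with open(path, "w") as fh:
        for pair in panel.pairs:
            name = pair.site.name
            fh.write(f">{name}_F\n{pair.linkered_fwd or pair.fwd_seq}\n")
            fh.write(f">{name}_R\n{pair.linkered_rev or pair.rev_seq}\n")
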