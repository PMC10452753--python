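"""Minimal MedDRA PT -> SOC mapping and related static tables.

MedDRA itself is proprietary and cannot be redistributed, so this module
bundles only the slice the renal/urinary analysis needs: the 26 renal and
urinary preferred terms under study, plus the common background PTs the
synthetic corpus draws from. A full user-supplied mapping can be passed to
any function that takes ``pt_to_soc``; unknown PTs map to ``UNMAPPED_SOC``.
"""
from __future__ import annotations

RENAL_SOC = "Renal and urinary disorders"
UNMAPPED_SOC = "UNMAPPED"

#: The renal/urinary PTs observed for the two study drugs.
RENAL_PTS: frozenset[str] = frozenset(
    {
        "Acute kidney injury",
        "Anuria",
        "Bladder disorder",
        "Chromaturia",
        "Chronic kidney disease",
        "Dysuria",
        "Haematuria",
        "Haemorrhage urinary tract",
        "Hydronephrosis",
        "Micturition disorder",
        "Micturition urgency",
        "Nephrolithiasis",
        "Nephrotic syndrome",
        "Nocturia",
        "Oliguria",
        "Pollakiuria",
        "Prerenal failure",
        "Proteinuria",
        "Renal disorder",
        "Renal failure",
        "Renal impairment",
        "Renal pain",
        "Urinary incontinence",
        "Urinary retention",
        "Urinary tract obstruction",
        "Urine odour abnormal",
    }
)

#: Background PTs (with their SOCs) used when synthesising corpora; these are
#: common adverse events of oral kinase inhibitors and cytotoxics in mCRC.
_BACKGROUND_PT_SOC: dict[str, str] = {
    "Nausea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Abdominal pain": "Gastrointestinal disorders",
    "Stomatitis": "Gastrointestinal disorders",
    "Fatigue": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
    "Disease progression": "General disorders and administration site conditions",
    "Palmar-plantar erythrodysaesthesia syndrome": "Skin and subcutaneous tissue disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Dermatitis acneiform": "Skin and subcutaneous tissue disorders",
    "Alopecia": "Skin and subcutaneous tissue disorders",
    "Hypertension": "Vascular disorders",
    "Haemorrhage": "Vascular disorders",
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Dehydration": "Metabolism and nutrition disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Dysphonia": "Respiratory, thoracic and mediastinal disorders",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Back pain": "Musculoskeletal and connective tissue disorders",
    "Anaemia": "Blood and lymphatic system disorders",
    "Thrombocytopenia": "Blood and lymphatic system disorders",
    "Weight decreased": "Investigations",
    "Blood bilirubin increased": "Investigations",
    "Hepatic function abnormal": "Hepatobiliary disorders",
    "Urinary tract infection": "Infections and infestations",
}

#: Bundled PT -> SOC table: renal PTs plus synthesis background PTs.
PT_TO_SOC: dict[str, str] = {pt: RENAL_SOC for pt in RENAL_PTS}
PT_TO_SOC.update(_BACKGROUND_PT_SOC)

#: Renal/urinary PTs present in each drug's FDA Full Prescribing Information
#: at the time of the study ("expected" ADRs). Encorafenib's US label lists
#: no renal/urinary PT, hence the empty set (its EMA SmPC differs, but
#: expectedness here follows the FDA label). Editable via config.
LABEL_EXPECTED_PTS: dict[str, frozenset[str]] = {
    "REG": frozenset(
        {
            "Proteinuria",
            "Haematuria",
            "Haemorrhage urinary tract",
            "Renal pain",
            "Nephrotic syndrome",
        }
    ),
    "ENC": frozenset(),
}

#: ISO-2 country code -> continent, covering the codes that occur in the
#: bundled synthetic corpora and the common FAERS reporter countries.
COUNTRY_TO_CONTINENT: dict[str, str] = {
    # North America
    "US": "North America", "CA": "North America", "MX": "North America",
    "PR": "North America",
    # Asia
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "TH": "Asia", "SG": "Asia", "PH": "Asia", "IL": "Asia", "SA": "Asia",
    # Europe
    "IT": "Europe", "FR": "Europe", "DE": "Europe", "GB": "Europe",
    "ES": "Europe", "NL": "Europe", "PL": "Europe", "SE": "Europe",
    "CH": "Europe", "AT": "Europe", "BE": "Europe", "DK": "Europe",
    "PT": "Europe", "GR": "Europe", "IE": "Europe", "NO": "Europe",
    "FI": "Europe", "CZ": "Europe", "HU": "Europe", "RO": "Europe",
    # South America
    "BR": "South America", "AR": "South America", "CO": "South America",
    "CL": "South America", "PE": "South America", "VE": "South America",
    # Oceania
    "AU": "Oceania", "NZ": "Oceania",
    # Africa
    "ZA": "Africa", "EG": "Africa", "NG": "Africa", "MA": "Africa",
    "TN": "Africa", "KE": "Africa", "DZ": "Africa",
}


def soc_of(pt: str, pt_to_soc: dict[str, str] | None = None) -> str:
    """SOC of a preferred term under the given (or bundled) mapping."""
    table = PT_TO_SOC if pt_to_soc is None else pt_to_soc
    return table.get(pt, UNMAPPED_SOC)


def continent_of(country: str) -> str:
    if not country:
        return "Not specified"
    return COUNTRY_TO_CONTINENT.get(country.upper(), "Not specified")
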