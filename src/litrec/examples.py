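"""Documented example inputs.

The toolkit ingests abstract tables; it deliberately ships no network
retrieval code.  The constants below are example PubMed query strings a
user could run themselves (e.g. with Bio.Entrez from Biopython) to
assemble a multilingual COVID-19 abstract collection, kept here purely
as documentation of the intended upstream step.
"""

# Narrow collection: abstracts directly about COVID-19.
PUBMED_QUERY_COVID19_EN = "covid-19 AND English [LANG]"
PUBMED_QUERY_COVID19_EN_PT = "covid-19 AND English [LANG] AND Portuguese [LANG]"
PUBMED_QUERY_COVID19_EN_ES = "covid-19 AND English [LANG] AND Spanish [LANG]"

# Broad collection: abstracts directly and indirectly related.
_BROAD_TERMS = (
    "2019 Novel Coronavirus Disease OR 2019 Novel Coronavirus Infection OR "
    "2019-nCoV Disease OR 2019-nCoV Infection OR COVID-19 Pandemic OR "
    "COVID-19 Pandemics OR COVID-19 Virus Disease OR COVID-19 Virus OR "
    "Infection OR COVID19 OR Coronavirus Disease 2019 OR "
    "Coronavirus Disease-19 OR SARS Coronavirus 2 Infection OR "
    "SARS-CoV-2 Infection"
)
PUBMED_QUERY_BROAD_EN = f"{_BROAD_TERMS} AND English [LANG]"
PUBMED_QUERY_BROAD_EN_PT = (
    f"{_BROAD_TERMS} AND English [LANG] AND Portuguese [LANG]"
)
PUBMED_QUERY_BROAD_EN_ES = (
    f"{_BROAD_TERMS} AND English [LANG] AND Spanish [LANG]"
)
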