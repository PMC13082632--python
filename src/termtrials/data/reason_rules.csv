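category,pattern,priority
evidence_of_futility,futilit,10
evidence_of_futility,lack of efficacy,20
evidence_of_futility,insufficient efficacy,20
evidence_of_futility,unlikely to (meet|reach) (the |its )?primary endpoint,30
evidence_of_futility,no (treatment )?benefit (was )?(observed|seen|found),30
external_evidence,external (evidence|data|trial results),10
external_evidence,results (of|from) (another|a similar|other) (trial|stud),20
external_evidence,newly published (evidence|data|results),20
external_evidence,evidence from other (trials|studies),20
evidence_of_harm,safety (concern|signal|issue|reasons)?,10
evidence_of_harm,toxicit,10
evidence_of_harm,serious adverse,20
evidence_of_harm,unacceptable (risk|harm|side effects),20
internal_evidence_unspecified,interim (analysis|review|data|results),10
internal_evidence_unspecified,internal (evidence|data|review),20
internal_evidence_unspecified,(dsmb|data monitoring committee) recommendation,30
evidence_of_benefit,evidence of benefit,10
evidence_of_benefit,met (its |the )?primary endpoint (early|ahead of schedule),20
evidence_of_benefit,overwhelming efficacy,20
evidence_of_benefit,benefit (was )?demonstrated,30
evidence_of_benefit,efficacy (goal|objective) (was )?met,30
low_accrual,accrual,10
low_accrual,recruit,10
low_accrual,enrol,10
low_accrual,lack of (eligible )?(patients|participants|subjects),20
lack_of_funding,fund,10
lack_of_funding,financ,10
lack_of_funding,budget,20
lack_of_funding,grant (expired|ended|not renewed),30
pi_departure,investigator('s)? (left|departed|departure|relocat),10
pi_departure,departure of the (principal |study )?investigator,20
pi_departure,pi (left|departed|moved),20
lack_of_investigational_product,(study drug|investigational product|study medication) (supply|shortage|unavailab|no longer available),10
lack_of_investigational_product,supply of (the )?(study drug|investigational product),20
lack_of_investigational_product,drug supply,20
lack_of_investigational_product,product (was )?(discontinued|withdrawn from the market|no longer manufactured),30
admin_logistical_technical,administrativ,10
admin_logistical_technical,logistic,10
admin_logistical_technical,technical (issue|problem|difficult),20
admin_logistical_technical,(sponsor|company|business) decision,20
admin_logistical_technical,strateg,20
admin_logistical_technical,site clos,30
admin_logistical_technical,staffing,30
admin_logistical_technical,contract (issue|disput|ended),30
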