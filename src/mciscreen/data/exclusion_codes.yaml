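# Default structured-code lists for cohort eligibility filters.
#
# The filters are named by condition; the codes are configuration, not a
# canonical value set -- replace them with the site's own groupers.  The
# synthetic corpus generator plants exactly these codes, so the defaults make
# generated data and cohort filters agree out of the box.
mci_diagnosis:
  - G31.84
  - "331.83"
adrd_diagnosis:
  - F03
  - G30.9
  - "290.0"
  - F01.50
parkinsons_diagnosis:
  - G20
psychosis_diagnosis:
  - F29
  - F20.9
bipolar_diagnosis:
  - F31.9
ad_medication:
  - donepezil
  - memantine
  - rivastigmine
  - galantamine
antipsychotic_medication:
  - haloperidol
  - risperidone
  - quetiapine
  - olanzapine
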