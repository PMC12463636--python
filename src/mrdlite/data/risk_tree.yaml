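# Default LLAG-077-style risk-stratification trees.
#
# Rules stated by the protocol figure legend are encoded verbatim:
# prednisone poor response, CNS3, day-33 marrow blasts >5%, and (UPDATED
# workflow only) re-classification by the day-15 MRD category. Numeric
# age/WBC branch points are NOT printed in the protocol summary; the ones
# below are placeholders marked ASSUMED and are meant to be overridden per
# site. Leaves are risk groups: VLR < LR < IR < HR.
#
# Node fields: id, feature, op (eq/ne/lt/le/gt/ge), value, then, else.
# Leaf fields: risk, or defer (re-enter another workflow's tree).
workflows:
  ORIGINAL:
    id: orig_prednisone
    feature: prednisone_response
    op: eq
    value: POOR
    then: {risk: HR}
    else:
      id: orig_cns3
      feature: cns_class
      op: eq
      value: CNS3
      then: {risk: HR}
      else:
        id: orig_day33
        feature: day33_marrow_blast_pct
        op: gt
        value: 5.0
        then: {risk: HR}
        else:
          id: orig_infant          # ASSUMED cutoff
          feature: age_years
          op: lt
          value: 1.0
          then: {risk: HR}
          else:
            id: orig_wbc           # ASSUMED cutoff
            feature: wbc_per_ul
            op: ge
            value: 50000.0
            then: {risk: IR}
            else:
              id: orig_age_high    # ASSUMED cutoff
              feature: age_years
              op: ge
              value: 10.0
              then: {risk: IR}
              else:
                id: orig_cns2      # ASSUMED mapping
                feature: cns_class
                op: eq
                value: CNS2
                then: {risk: IR}
                else: {risk: LR}

  UPDATED:
    id: upd_reportable
    feature: mrd_reportable
    op: eq
    value: false
    then: {defer: ORIGINAL}        # unreportable MRD: fall back to clinical tree
    else:
      id: upd_prednisone
      feature: prednisone_response
      op: eq
      value: POOR
      then: {risk: HR}
      else:
        id: upd_cns3
        feature: cns_class
        op: eq
        value: CNS3
        then: {risk: HR}
        else:
          id: upd_day33
          feature: day33_marrow_blast_pct
          op: gt
          value: 5.0
          then: {risk: HR}
          else:
            id: upd_infant         # ASSUMED cutoff
            feature: age_years
            op: lt
            value: 1.0
            then: {risk: HR}
            else:
              id: upd_mrd_gt10
              feature: mrd_category
              op: eq
              value: POS_GT_10
              then: {risk: HR}
              else:
                id: upd_mrd_mid
                feature: mrd_category
                op: eq
                value: POS_0.1_10
                then: {risk: IR}
                else:
                  id: upd_mrd_low
                  feature: mrd_category
                  op: eq
                  value: POS_0.01_0.1
                  then:
                    id: upd_low_wbc      # ASSUMED cutoff
                    feature: wbc_per_ul
                    op: ge
                    value: 50000.0
                    then: {risk: IR}
                    else:
                      id: upd_low_age    # ASSUMED cutoff
                      feature: age_years
                      op: ge
                      value: 10.0
                      then: {risk: IR}
                      else:
                        id: upd_low_cns2 # ASSUMED mapping
                        feature: cns_class
                        op: eq
                        value: CNS2
                        then: {risk: IR}
                        else: {risk: LR}
                  else:
                    id: upd_neg_wbc      # ASSUMED cutoff
                    feature: wbc_per_ul
                    op: ge
                    value: 50000.0
                    then: {risk: IR}
                    else:
                      id: upd_neg_age    # ASSUMED cutoff
                      feature: age_years
                      op: ge
                      value: 10.0
                      then: {risk: IR}
                      else:
                        id: upd_neg_cns2 # ASSUMED mapping
                        feature: cns_class
                        op: eq
                        value: CNS2
                        then: {risk: IR}
                        else: {risk: VLR}
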