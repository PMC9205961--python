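trait,kind,ordinal,state,cohorts,diagnostic_cohorts
primary_covert_pattern,plumage,0,Buff edged (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
primary_covert_pattern,plumage,1,Plain/solid (hybrid/mallard),MI|MA|FI|FA,MI|MA|FI|FA
lesser_covert_pattern,plumage,0,Buff edged (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
lesser_covert_pattern,plumage,1,Plain/solid (mallard),MI|MA|FI|FA,MI|MA|FI|FA
greater_covert_pattern,plumage,0,Buffy or part white across coverts (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
greater_covert_pattern,plumage,1,Complete white across coverts (hybrid/mallard),MI|MA|FI|FA,MI|MA|FI|FA
speculum_color,plumage,0,Green (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
speculum_color,plumage,1,No green (hybrid/mallard),MI|MA|FI|FA,MI|MA|FI|FA
percent_green_in_head,plumage,0,No green (Mexican duck),MI|MA,MI|MA
percent_green_in_head,plumage,1,1-25% green,MI|MA,MI|MA
percent_green_in_head,plumage,2,26-50% green,MI|MA,MI|MA
percent_green_in_head,plumage,3,>50% green (mallard),MI|MA,MI|MA
face_neck_pattern,plumage,0,Slightly patterned (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
face_neck_pattern,plumage,1,Continuously strong pattern (hybrid/mallard),MI|MA|FI|FA,MI|MA|FI|FA
black_spots_around_bill,plumage,0,Absent (Mexican duck),MI|MA,MI|MA
black_spots_around_bill,plumage,1,Present (mallard),MI|MA,MI|MA
back_pattern_color,plumage,0,Chevron patterned or buff/brown edges (Mexican duck),MI|MA|FI,MI|MA|FI
back_pattern_color,plumage,1,Solid or light patterned (mallard),MI|MA|FI,MI|MA|FI
scapular_pattern,plumage,0,Chevron patterned or buff/brown edges (Mexican duck),MI|MA|FI,MI|MA|FI
scapular_pattern,plumage,1,Solid or light patterned (mallard),MI|MA|FI,MI|MA|FI
rump,plumage,0,Brown with buffy chevrons and buffy edges (Mexican duck),MI|MA|FI,MI|MA|FI
rump,plumage,1,Black with rufous chevrons and rufous edges (hybrid),MI|MA|FI,MI|MA|FI
rump,plumage,2,Solid black (mallard),MI|MA|FI,MI|MA|FI
outer_tail_feather_edges,plumage,0,Buff edged (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
outer_tail_feather_edges,plumage,1,White edged (mallard),MI|MA|FI|FA,MI|MA|FI|FA
central_tail_feather_curl,plumage,0,Not raised (Mexican duck),MI|MA,MI|MA
central_tail_feather_curl,plumage,1,Slightly raised (intermediate),MI|MA,MI|MA
central_tail_feather_curl,plumage,2,More than half curl (mallard),MI|MA,MI|MA
breast_feather_pattern,plumage,0,Strong internal pattern (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
breast_feather_pattern,plumage,1,Slight internal pattern with whitish edges (mallard),MI|MA|FI|FA,MI|MA|FI|FA
breast_belly_pattern,plumage,0,Uniform (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
breast_belly_pattern,plumage,1,Breast and belly different color (mallard),MI|MA|FI|FA,MI|MA|FI|FA
flank_feather_pattern,plumage,0,Chevron patterned (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
flank_feather_pattern,plumage,1,Slight internal marking (mallard),MI|MA|FI|FA,MI|MA|FI|FA
undertail_covert_pattern,plumage,0,Chevron patterned (Mexican duck),MI|MA|FI|FA,MI|MA|FI|FA
undertail_covert_pattern,plumage,1,Spotted to subtle internal marking (hybrid),MI|MA|FI|FA,MI|MA|FI|FA
undertail_covert_pattern,plumage,2,Gray-black or unpatterned (mallard),MI|MA|FI|FA,MI|MA|FI|FA
bill_length,structural,,mm,MI|MA|FI|FA,
bill_width,structural,,mm,MI|MA|FI|FA,
central_tail_feather_length,structural,,mm,MI|MA|FI|FA,
culmen_nares,structural,,mm,MI|MA|FI|FA,
tarsus_length,structural,,mm,MI|MA|FI|FA,
wing_arc,structural,,mm,MI|MA|FI|FA,
mass,mass,,g,MI|MA|FI|FA,
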