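position,variable,mean,sd
DB,age,27.8,2.8
DB,body_mass,83.4,6.6
DB,stretch_stature,175.5,5.5
DB,sitting_height,92.3,3.0
DB,arm_span,179.9,6.8
DB,biacromial,40.7,1.9
DB,transverse_chest,29.8,2.5
DB,ap_chest_depth,21.2,1.5
DB,biiliocristal,28.3,1.7
DB,humerus,7.0,0.4
DB,femur,10.0,0.3
DB,head_girth,56.3,2.4
DB,arm_relaxed,35.2,1.5
DB,arm_flexed_tensed,37.9,2.5
DB,forearm_girth,29.1,1.2
DB,chest_girth,102.6,4.5
DB,waist_girth,86.4,4.6
DB,thigh_girth,62.5,2.4
DB,calf_girth,37.7,2.6
DB,triceps_sf,8.9,3.1
DB,subscapular_sf,11.2,3.1
DB,biceps_sf,4.0,1.2
DB,iliac_crest_sf,14.1,4.7
DB,supraspinale_sf,7.6,2.5
DB,abdominal_sf,18.8,7.8
DB,thigh_sf,10.7,3.5
DB,calf_sf,6.1,2.3
DL,age,28.6,3.9
DL,body_mass,111.3,16.2
DL,stretch_stature,183.4,4.9
DL,sitting_height,96.3,2.9
DL,arm_span,188.8,5.7
DL,biacromial,43.5,1.9
DL,transverse_chest,34.0,3.3
DL,ap_chest_depth,24.5,2.3
DL,biiliocristal,32.0,2.2
DL,humerus,7.6,0.4
DL,femur,10.8,0.7
DL,head_girth,57.5,1.5
DL,arm_relaxed,40.4,2.8
DL,arm_flexed_tensed,42.2,2.7
DL,forearm_girth,31.7,2.5
DL,chest_girth,117.0,7.7
DL,waist_girth,101.2,9.6
DL,thigh_girth,70.3,5.3
DL,calf_girth,41.7,2.9
DL,triceps_sf,12.5,6.3
DL,subscapular_sf,21.0,8.4
DL,biceps_sf,6.6,3.1
DL,iliac_crest_sf,25.8,10.0
DL,supraspinale_sf,17.0,8.3
DL,abdominal_sf,29.9,9.7
DL,thigh_sf,15.6,7.3
DL,calf_sf,12.3,5.4
LB,age,27.8,2.3
LB,body_mass,93.4,7.4
LB,stretch_stature,179.6,4.1
LB,sitting_height,94.2,2.8
LB,arm_span,183.0,6.0
LB,biacromial,42.0,1.6
LB,transverse_chest,30.7,1.7
LB,ap_chest_depth,22.5,2.9
LB,biiliocristal,29.7,1.7
LB,humerus,7.4,0.4
LB,femur,10.3,0.6
LB,head_girth,57.5,1.0
LB,arm_relaxed,37.6,2.1
LB,arm_flexed_tensed,39.9,1.9
LB,forearm_girth,30.7,1.2
LB,chest_girth,107.1,5.1
LB,waist_girth,91.3,5.1
LB,thigh_girth,65.2,2.4
LB,calf_girth,39.6,2.2
LB,triceps_sf,9.7,3.3
LB,subscapular_sf,14.8,4.6
LB,biceps_sf,4.6,1.4
LB,iliac_crest_sf,19.8,7.2
LB,supraspinale_sf,11.3,4.9
LB,abdominal_sf,23.5,7.6
LB,thigh_sf,11.9,4.0
LB,calf_sf,8.6,3.5
OL,age,28.5,2.7
OL,body_mass,127.6,16.8
OL,stretch_stature,185.0,6.1
OL,sitting_height,96.5,2.9
OL,arm_span,189.5,6.2
OL,biacromial,44.1,2.4
OL,transverse_chest,35.2,2.4
OL,ap_chest_depth,26.5,2.3
OL,biiliocristal,34.2,2.0
OL,humerus,7.8,0.5
OL,femur,11.3,0.9
OL,head_girth,58.8,2.0
OL,arm_relaxed,42.3,2.6
OL,arm_flexed_tensed,43.7,2.5
OL,forearm_girth,34.2,5.8
OL,chest_girth,125.7,7.9
OL,waist_girth,112.3,8.1
OL,thigh_girth,74.3,3.9
OL,calf_girth,43.5,3.8
OL,triceps_sf,17.7,5.9
OL,subscapular_sf,31.2,10.7
OL,biceps_sf,9.5,3.7
OL,iliac_crest_sf,33.3,7.2
OL,supraspinale_sf,26.0,6.2
OL,abdominal_sf,36.5,7.0
OL,thigh_sf,22.2,8.6
OL,calf_sf,16.4,7.1
QB,age,28.0,1.6
QB,body_mass,86.0,11.0
QB,stretch_stature,175.9,2.0
QB,sitting_height,92.9,2.3
QB,arm_span,180.1,2.1
QB,biacromial,40.6,1.7
QB,transverse_chest,30.3,2.3
QB,ap_chest_depth,21.8,3.2
QB,biiliocristal,29.0,2.5
QB,humerus,7.3,0.2
QB,femur,10.1,0.7
QB,head_girth,56.4,1.4
QB,arm_relaxed,34.8,2.3
QB,arm_flexed_tensed,35.2,4.5
QB,forearm_girth,29.3,1.5
QB,chest_girth,102.8,5.5
QB,waist_girth,89.9,8.7
QB,thigh_girth,62.6,4.8
QB,calf_girth,37.8,3.0
QB,triceps_sf,12.0,5.0
QB,subscapular_sf,15.4,8.5
QB,biceps_sf,5.9,2.4
QB,iliac_crest_sf,18.8,8.1
QB,supraspinale_sf,11.5,6.3
QB,abdominal_sf,23.0,10.8
QB,thigh_sf,12.7,4.7
QB,calf_sf,7.3,1.5
RB,age,27.7,2.1
RB,body_mass,84.1,10.8
RB,stretch_stature,173.9,7.0
RB,sitting_height,91.2,4.2
RB,arm_span,178.4,7.1
RB,biacromial,41.2,2.1
RB,transverse_chest,29.6,2.7
RB,ap_chest_depth,21.7,2.5
RB,biiliocristal,28.4,2.1
RB,humerus,7.0,0.4
RB,femur,10.0,0.5
RB,head_girth,56.0,1.4
RB,arm_relaxed,35.6,2.8
RB,arm_flexed_tensed,37.7,2.6
RB,forearm_girth,29.1,1.5
RB,chest_girth,103.1,7.9
RB,waist_girth,88.5,7.0
RB,thigh_girth,61.8,3.9
RB,calf_girth,37.5,2.8
RB,triceps_sf,8.9,2.7
RB,subscapular_sf,13.4,5.5
RB,biceps_sf,4.9,1.7
RB,iliac_crest_sf,17.7,8.8
RB,supraspinale_sf,9.9,5.4
RB,abdominal_sf,21.1,8.1
RB,thigh_sf,11.0,3.2
RB,calf_sf,6.7,2.0
WR,age,28.4,2.8
WR,body_mass,83.2,7.9
WR,stretch_stature,177.8,5.0
WR,sitting_height,92.7,3.5
WR,arm_span,180.7,5.6
WR,biacromial,41.2,1.6
WR,transverse_chest,29.3,2.2
WR,ap_chest_depth,21.4,1.9
WR,biiliocristal,28.4,1.4
WR,humerus,7.0,0.4
WR,femur,9.9,0.5
WR,head_girth,57.1,2.0
WR,arm_relaxed,34.5,1.6
WR,arm_flexed_tensed,36.8,1.7
WR,forearm_girth,29.1,1.4
WR,chest_girth,101.9,4.7
WR,waist_girth,85.9,6.1
WR,thigh_girth,61.5,3.0
WR,calf_girth,37.6,1.8
WR,triceps_sf,8.3,2.7
WR,subscapular_sf,12.1,4.6
WR,biceps_sf,3.9,1.2
WR,iliac_crest_sf,14.3,7.2
WR,supraspinale_sf,8.1,4.2
WR,abdominal_sf,18.8,8.4
WR,thigh_sf,9.6,3.6
WR,calf_sf,5.9,2.2
Total,age,28.1,2.8
Total,body_mass,97.1,19.8
Total,stretch_stature,179.4,6.3
Total,sitting_height,94.0,3.6
Total,arm_span,183.6,7.3
Total,biacromial,42.1,2.3
Total,transverse_chest,31.4,3.3
Total,ap_chest_depth,22.9,3.0
Total,biiliocristal,30.2,2.8
Total,humerus,7.3,0.5
Total,femur,10.4,0.8
Total,head_girth,57.2,2.0
Total,arm_relaxed,37.6,3.6
Total,arm_flexed_tensed,39.6,3.5
Total,forearm_girth,30.6,3.2
Total,chest_girth,109.5,10.6
Total,waist_girth,94.1,11.6
Total,thigh_girth,66.0,5.9
Total,calf_girth,39.6,3.5
Total,triceps_sf,11.1,5.3
Total,subscapular_sf,17.3,9.4
Total,biceps_sf,5.6,3.0
Total,iliac_crest_sf,20.8,10.0
Total,supraspinale_sf,13.2,8.2
Total,abdominal_sf,24.7,10.3
Total,thigh_sf,13.5,6.8
Total,calf_sf,9.4,5.5
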