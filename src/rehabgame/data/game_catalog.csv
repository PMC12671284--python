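name,axis,start_difficulty,response_time,clicker,precision,distractor,activity_type
Abundante,horizontal,moderate,self_paced_time_limited,yes,moderate,no,color_matching_by_directional_aiming
Action Ball,horizontal,moderate,fast,yes,moderate,yes,brick_buster
Aqua Ball,horizontal,easy,moderate,yes,moderate,yes,brick_buster
Astro Bugz Revenge,horizontal,moderate,slow,yes,moderate,no,color_matching_by_directional_aiming
Birds Town,horizontal,moderate,moderate,yes,moderate,no,color_matching_by_directional_aiming
Brave Piglet,vertical,easy,fast,yes,low,yes,shooting
Bricks of Egypt,horizontal,moderate,fast,yes,moderate,yes,brick_buster
Butterfly Escape,horizontal,moderate,moderate,yes,moderate,no,color_matching_by_directional_aiming
Egyptian Ball,horizontal,moderate,fast,yes,moderate,yes,brick_buster
Invadazoid,horizontal,moderate,fast,yes,moderate,yes,brick_buster
Jar of Marbles,horizontal,easy,self_paced_time_unlimited,yes,moderate,no,color_matching_by_directional_aiming
Jet Jumper,horizontal,difficult,fast,yes,high,yes,steering_and_jumping
Luxor HD,horizontal,moderate,moderate,yes,moderate,no,color_matching_by_directional_aiming
Ricochet Recharge,horizontal,moderate,fast,yes,moderate,yes,brick_buster
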